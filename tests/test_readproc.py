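"""Demultiplexing, barcode matching, assignment, counting: tie rules,
conservation, and brute-force oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from pathscreen import SimConfig, build_library, emit_screen_reads, make_sample_sheet, simulate_counts
from pathscreen.fastq import read_sequences
from pathscreen.readproc import (
    AMBIGUOUS,
    BarcodeMatcher,
    SampleSheet,
    build_assignment,
    count_features,
    demultiplex,
    extract_between,
    hamming,
    match_barcode,
)
from pathscreen.simdata import FLANK3, FLANK5, LibraryDef, assignment_amplicon


def edit_distance_oracle(a: str, b: str, cap: int = 3) -> int:
    """Plain Wagner-Fischer DP, capped at `cap` (values above are reported
    as cap + 1). Independent of the matcher implementation."""
    la, lb = len(a), len(b)
    if abs(la - lb) > cap:
        return cap + 1
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a[i - 1] != b[j - 1]))
        if min(cur) > cap:
            return cap + 1
        prev = cur
    return min(prev[lb], cap + 1)


def brute_force_match(seq: str, refs: pd.DataFrame, max_edit: int):
    best_d, best, tie = max_edit + 1, None, False
    for vid, ref in zip(refs["vector_id"], refs["barcode"]):
        d = edit_distance_oracle(seq, ref, cap=max_edit)
        if d < best_d:
            best_d, best, tie = d, vid, False
        elif d == best_d:
            tie = True
    if best is None or best_d > max_edit:
        return None
    return AMBIGUOUS if tie else best


def _sheet(codes, conditions=None):
    n = len(codes)
    rows = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "code": codes,
            "condition": conditions or ["TTX"] * n,
            "replicate": [f"r{i}" for i in range(n)],
        }
    )
    return rows


class TestDemultiplex:
    def test_exact_and_hamming1_assignment(self):
        sheet = SampleSheet(_sheet(["AAAAAAAAAAAA", "CCCCCCCCCCCC"]))
        reads = [
            "AAAAAAAAAAAA" + "G" * 40,  # exact
            "AAAAAAAAAAAT" + "G" * 40,  # Hamming 1 from s0
            "ACCAAAAAAAAA" + "G" * 40,  # Hamming 2: unassigned
        ]
        per, un, tally = demultiplex(reads, sheet, max_code_mm=1)
        assert len(per["s0"]) == 2 and len(per["s1"]) == 0
        assert len(un) == 1
        assert tally == {"total": 3, "assigned": 2, "unassigned": 1}
        # brute-force neighbor scan agrees for the Hamming-1 read
        code = reads[1][:12]
        hits = [c for c in ["AAAAAAAAAAAA", "CCCCCCCCCCCC"] if hamming(code, c) <= 1]
        assert hits == ["AAAAAAAAAAAA"]

    def test_tie_between_two_codes_is_unassigned(self):
        # codes at Hamming distance 2; a read between them is ambiguous
        rows = _sheet(["AAAAAAAAAAAA", "AATTAAAAAAAA"])
        sheet = SampleSheet(rows, max_code_mm=0)  # bypass separation check
        read = "AATAAAAAAAAA" + "G" * 40  # Hamming 1 to both
        per, un, tally = demultiplex([read], sheet, max_code_mm=1)
        assert tally["assigned"] == 0 and len(un) == 1

    def test_duplicate_codes_rejected_at_load(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleSheet(_sheet(["AAAAAAAAAAAA", "AAAAAAAAAAAA"]))

    def test_close_codes_rejected_at_load(self):
        with pytest.raises(ValueError, match="within"):
            SampleSheet(_sheet(["AAAAAAAAAAAA", "AAAAAAAAAATT"]), max_code_mm=1)

    def test_conservation(self, small_config, small_library, small_counts, small_sheet, tmp_path):
        lib, _ = small_library
        path = tmp_path / "r.fastq"
        sheet_df = make_sample_sheet(small_counts.design, small_config.seed)
        n = emit_screen_reads(small_counts, lib, sheet_df, small_config, str(path))
        per, un, tally = demultiplex(read_sequences(str(path)), small_sheet)
        assert tally["assigned"] + tally["unassigned"] == tally["total"] == n


@pytest.fixture(scope="module")
def match_library():
    cfg = SimConfig(n_genes=12, shrnas_per_gene=(5,), seed=21)
    return build_library(cfg)[0]


@pytest.fixture(scope="module")
def assign_library():
    return build_library(SimConfig(n_genes=10, shrnas_per_gene=(5,), seed=31))[0]


class TestMatchBarcode:

    def test_exact_match(self, match_library):
        row = match_library.vectors.iloc[3]
        assert match_barcode(row["barcode"], match_library) == row["vector_id"]

    def test_one_substitution_unique_best_hit(self, match_library):
        row = match_library.vectors.iloc[5]
        bc = row["barcode"]
        mut = "T" + bc[1:] if bc[0] != "T" else "A" + bc[1:]
        assert match_barcode(mut, match_library) == row["vector_id"]
        assert brute_force_match(mut, match_library.vectors, 2) == row["vector_id"]

    def test_two_refs_at_distance_two_is_ambiguous(self):
        refs = pd.DataFrame(
            {
                "vector_id": ["v1", "v2"],
                "barcode": ["AAAAAAAAAA", "AAAAAAAATT"],
                "shrna_id": ["v1", "v2"],
                "guide": ["", ""],
                "gene": ["g1", "g2"],
                "is_calibrator": [False, False],
            }
        )
        lib = LibraryDef(refs, barcode_length=10)
        # distance 2 to v1 (2 subs) and 2 to v2 (2 subs)
        query = "AAAAAAAAGG"
        # confirm the construction with the oracle before asserting the tie
        assert edit_distance_oracle(query, "AAAAAAAAAA") == 2
        assert edit_distance_oracle(query, "AAAAAAAATT") == 2
        assert BarcodeMatcher(lib, max_edit=2).match(query) == AMBIGUOUS

    def test_nothing_within_max_edit_is_none(self, match_library):
        assert match_barcode("G" * 35, match_library) is None

    def test_matcher_equals_brute_force_on_random_reads(self, match_library):
        """Oracle equivalence: the tiered matcher must reproduce a full
        edit-distance scan on reads with 0-3 errors (subs and indels) and
        on unrelated random sequences."""
        rng = np.random.default_rng(42)
        matcher = BarcodeMatcher(match_library, max_edit=2)
        refs = match_library.vectors
        bases = "ACGT"
        n_checked = 0
        for _ in range(1000):
            kind = rng.integers(0, 5)
            if kind == 4:
                seq = "".join(rng.choice(list(bases), 35))
            else:
                seq = list(refs["barcode"].iloc[rng.integers(0, len(refs))])
                for _e in range(kind):  # 0-3 edits
                    op = rng.integers(0, 3)
                    pos = rng.integers(0, len(seq))
                    if op == 0:
                        seq[pos] = bases[rng.integers(0, 4)]
                    elif op == 1 and len(seq) > 30:
                        del seq[pos]
                    else:
                        seq.insert(pos, bases[rng.integers(0, 4)])
                seq = "".join(seq)
            assert matcher.match(seq) == brute_force_match(seq, refs, 2)
            n_checked += 1
        assert n_checked == 1000

    def test_match_independent_of_reference_order(self, match_library):
        shuffled = LibraryDef(
            match_library.vectors.sample(frac=1.0, random_state=1).reset_index(drop=True),
            match_library.barcode_length,
        )
        rng = np.random.default_rng(3)
        for _ in range(50):
            bc = match_library.vectors["barcode"].iloc[rng.integers(0, len(match_library.vectors))]
            mut = list(bc)
            mut[rng.integers(0, 35)] = "ACGT"[rng.integers(0, 4)]
            mut = "".join(mut)
            assert match_barcode(mut, match_library) == match_barcode(mut, shuffled)


class TestAssignment:

    def _reads(self, assign_library, spec):
        """spec: list of (barcode, guide, n)"""
        out = []
        for bc, guide, n in spec:
            out += [assignment_amplicon(bc, guide)] * n
        return out

    def test_majority_vote_with_purity(self, assign_library):
        v = assign_library.vectors
        bc = v["barcode"].iloc[0]
        good, bad = v["guide"].iloc[0], v["guide"].iloc[1]
        reads = self._reads(assign_library, [(bc, good, 9), (bc, bad, 1)])
        table, report = build_assignment(reads, assign_library)
        row = table.set_index("barcode").loc[bc]
        assert row["status"] == "assigned"
        assert row["shrna_id"] == v["shrna_id"].iloc[0]
        assert row["purity"] == pytest.approx(0.9)
        assert row["support"] == 10

    def test_low_support_excluded(self, assign_library):
        v = assign_library.vectors
        reads = self._reads(assign_library, [(v["barcode"].iloc[0], v["guide"].iloc[0], 2)])
        table, _ = build_assignment(reads, assign_library)
        assert table["status"].iloc[0] == "low_support"

    def test_tied_vote_ambiguous(self, assign_library):
        v = assign_library.vectors
        reads = self._reads(assign_library, [(v["barcode"].iloc[0], v["guide"].iloc[0], 5),
                                      (v["barcode"].iloc[0], v["guide"].iloc[1], 5)])
        table, _ = build_assignment(reads, assign_library)
        assert table["status"].iloc[0] == "ambiguous"

    def test_no_parseable_reads_warns_empty(self, assign_library):
        with pytest.warns(UserWarning, match="no parseable"):
            table, report = build_assignment(["ACGT" * 20], assign_library)
        assert len(table) == 0
        assert report["gene_recovery"] == 0.0

    def test_full_roundtrip_recovers_every_pair(self, small_library, small_config, tmp_path):
        from pathscreen import emit_assignment_reads

        lib, _ = small_library
        path = tmp_path / "assign.fastq"
        emit_assignment_reads(lib, 5, small_config, str(path))
        table, report = build_assignment(read_sequences(str(path)), lib)
        assert report["gene_recovery"] == 1.0
        assigned = table[table["status"] == "assigned"]
        truth = dict(zip(lib.vectors["barcode"], lib.vectors["shrna_id"]))
        assert dict(zip(assigned["barcode"], assigned["shrna_id"])) == truth


class TestCountFeatures:
    def test_roundtrip_exact(self, small_config, small_library, small_counts, small_sheet, tmp_path):
        """error_rate=0: demux + match + count returns the simulated matrix."""
        lib, _ = small_library
        path = tmp_path / "rt.fastq"
        sheet_df = make_sample_sheet(small_counts.design, small_config.seed)
        emit_screen_reads(small_counts, lib, sheet_df, small_config, str(path))
        per, _, _ = demultiplex(read_sequences(str(path)), small_sheet)
        rec, tallies = count_features(per, lib, small_sheet)
        pd.testing.assert_frame_equal(
            rec.counts.loc[small_counts.counts.index, small_counts.counts.columns],
            small_counts.counts,
        )

    def test_column_sum_and_tally_conservation(self, small_library, small_sheet):
        lib, _ = small_library
        good = small_sheet.rows["code"].iloc[0] + FLANK5 + lib.vectors["barcode"].iloc[0] + FLANK3
        bad = small_sheet.rows["code"].iloc[0] + FLANK5 + "G" * 35 + FLANK3
        sample = small_sheet.sample_ids[0]
        reads = {sample: [good] * 8 + [bad] * 2}
        counts, tallies = count_features(reads, lib, small_sheet)
        assert counts.counts[sample].sum() == 8
        assert tallies[sample]["unmatched"] == 2
        assert tallies[sample]["total"] == 10

    def test_sample_with_no_reads_is_zero_column(self, small_library, small_sheet):
        lib, _ = small_library
        counts, _ = count_features({}, lib, small_sheet)
        assert (counts.counts == 0).all().all()

    def test_unknown_sample_id_fails(self, small_library, small_sheet):
        lib, _ = small_library
        with pytest.raises(ValueError, match="unknown sample"):
            count_features({"nope": []}, lib, small_sheet)

    def test_shrna_level_uses_assignment(self, small_library, small_sheet, small_config, tmp_path):
        from pathscreen import emit_assignment_reads

        lib, _ = small_library
        apath = tmp_path / "a.fastq"
        emit_assignment_reads(lib, 5, small_config, str(apath))
        assignment, _ = build_assignment(read_sequences(str(apath)), lib)
        code = small_sheet.rows["code"].iloc[0]
        sample = small_sheet.sample_ids[0]
        v = lib.vectors.iloc[0]
        reads = {sample: [code + FLANK5 + v["barcode"] + FLANK3] * 4}
        counts, _ = count_features(reads, lib, small_sheet, level="shrna", assignment=assignment)
        assert counts.counts.loc[v["shrna_id"], sample] == 4

    def test_error_reads_mostly_recovered(self, small_library):
        """>= 99% of reads with 0.5% per-base substitutions match their true
        vector at max_edit=2."""
        lib, _ = small_library
        cfg = SimConfig(n_genes=40, depth=20_000, error_rate=0.005, seed=23, n_replicates=1)
        _, eff = build_library(SimConfig(n_genes=40, seed=11))  # effects irrelevant here
        matcher = BarcodeMatcher(lib, max_edit=2)
        rng = np.random.default_rng(23)
        n, ok = 0, 0
        for _ in range(20_000):
            row = lib.vectors.iloc[rng.integers(0, len(lib.vectors))]
            seq = list(row["barcode"])
            for pos in np.nonzero(rng.random(35) < 0.005)[0]:
                seq[pos] = "ACGT"[rng.integers(0, 4)]
            n += 1
            if matcher.match("".join(seq)) == row["vector_id"]:
                ok += 1
        assert ok / n >= 0.99


def test_extract_between_tolerates_anchor_mismatch():
    inner = "ACGTACGTAC"
    seq = "TTTT" + "CCCGAGGC" + inner + "AAGCGGCC" + "TTTT"
    assert extract_between(seq, "CCCGAGGC", "AAGCGGCC") == inner
    damaged = seq.replace("CCCGAGGC", "CCCGAGGA")
    assert extract_between(damaged, "CCCGAGGC", "AAGCGGCC") == inner
    assert extract_between("A" * 40, "CCCGAGGC", "AAGCGGCC") is None
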