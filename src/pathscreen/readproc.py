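"""Raw reads to per-sample feature counts.

Stages: split reads by their 12-nt sample code (Hamming-tolerant,
ambiguity-aware), extract the vector barcode between fixed flanks, match it
against the reference library by minimal edit distance, and tally counts.
A separate amplicon run assigns barcodes to shRNA guides by majority vote.

Matching semantics: an exact barcode hit wins immediately; otherwise the
unique reference at minimal edit distance <= max_edit wins; ties are
ambiguous; nothing within max_edit is unmatched. The implementation is
tiered for speed (exact dict, Hamming-1 neighbor dict, full edlib scan) but
is exactly equivalent to a brute-force scan: between equal-length strings,
edit distance 1 is possible only via a substitution, so the Hamming-1 tier
decides distance-1 uniqueness correctly, and everything else falls through
to the full scan.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd

from .containers import CountMatrix
from .simdata import FLANK3, FLANK5, BC_ANCHOR_L, BC_ANCHOR_R, GUIDE_ANCHOR_L, GUIDE_ANCHOR_R, SAMPLE_CODE_LEN, LibraryDef

AMBIGUOUS = "__ambiguous__"


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class SampleSheet:
    """Sample_id / 12-nt code / condition / replicate / timepoint rows.

    Codes must be unique and pairwise separated by more than 2*max_code_mm
    so that mismatch-tolerant demultiplexing can never assign one read to
    two samples.
    """

    rows: pd.DataFrame
    max_code_mm: int = 1

    def __post_init__(self) -> None:
        req = {"sample_id", "code", "condition", "replicate"}
        if not req <= set(self.rows.columns):
            raise ValueError(f"sample sheet needs columns {sorted(req)}")
        if "timepoint" not in self.rows.columns:
            self.rows = self.rows.assign(timepoint=np.nan)
        codes = list(self.rows["code"])
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate codes in sample sheet")
        if any(len(c) != SAMPLE_CODE_LEN for c in codes):
            raise ValueError(f"codes must be {SAMPLE_CODE_LEN} nt")
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                if hamming(a, b) <= 2 * self.max_code_mm:
                    raise ValueError(
                        f"codes {a} and {b} are within 2*max_code_mm={2 * self.max_code_mm} mismatches"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows["sample_id"])

    def design(self) -> pd.DataFrame:
        return self.rows.set_index("sample_id")[["condition", "replicate", "timepoint"]]

    def to_tsv(self, path: str) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, max_code_mm: int = 1) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"code": str}), max_code_mm)


class CodeAssigner:
    """Assign a read to a sample by its leading code; exact dict first, then
    a Hamming scan over the sheet. A read is assigned iff exactly one code
    is within max_code_mm."""

    def __init__(self, sheet: SampleSheet, max_code_mm: int = 1):
        self.max_code_mm = max_code_mm
        self.exact = dict(zip(sheet.rows["code"], sheet.rows["sample_id"]))
        self.codes = list(zip(sheet.rows["code"], sheet.rows["sample_id"]))
        self._cache: dict[str, str | None] = {}

    def assign(self, read: str) -> str | None:
        code = read[:SAMPLE_CODE_LEN]
        hit = self.exact.get(code)
        if hit is not None:
            return hit
        if self.max_code_mm == 0:
            return None
        cached = self._cache.get(code, "?")
        if cached != "?":
            return cached
        best: str | None = None
        best_d = self.max_code_mm + 1
        tie = False
        for ref, sample in self.codes:
            d = hamming(code, ref)
            if d < best_d:
                best, best_d, tie = sample, d, False
            elif d == best_d:
                tie = True
        out = best if (best is not None and not tie) else None
        self._cache[code] = out
        return out


def demultiplex(
    reads: Iterable[str],
    sheet: SampleSheet,
    max_code_mm: int = 1,
) -> tuple[dict[str, list[str]], list[str], dict[str, int]]:
    """Split reads per sample. Returns (per-sample reads, unassigned reads,
    tally). Conservation: assigned + unassigned = total."""
    assigner = CodeAssigner(sheet, max_code_mm)
    per_sample: dict[str, list[str]] = {s: [] for s in sheet.sample_ids}
    unassigned: list[str] = []
    total = 0
    for read in reads:
        total += 1
        sample = assigner.assign(read)
        if sample is None:
            unassigned.append(read)
        else:
            per_sample[sample].append(read)
    tally = {"total": total, "assigned": total - len(unassigned), "unassigned": len(unassigned)}
    return per_sample, unassigned, tally


def extract_between(seq: str, left: str, right: str, max_anchor_mm: int = 1) -> str | None:
    """Extract the region between two anchors; each anchor may carry up to
    max_anchor_mm mismatches. Returns None if an anchor is not found."""
    i = seq.find(left)
    if i < 0:
        i = _fuzzy_find(seq, left, max_anchor_mm)
        if i < 0:
            return None
    start = i + len(left)
    j = seq.find(right, start)
    if j < 0:
        j = _fuzzy_find(seq, right, max_anchor_mm, start)
        if j < 0:
            return None
    return seq[start:j]


def _fuzzy_find(seq: str, pattern: str, max_mm: int, start: int = 0) -> int:
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        if hamming(seq[i:i + m], pattern) <= max_mm:
            return i
    return -1


class BarcodeMatcher:
    """Minimal-edit-distance barcode matching against a reference library."""

    def __init__(self, library: LibraryDef, max_edit: int = 2):
        self.max_edit = max_edit
        self.bc_len = library.barcode_length
        v = library.vectors
        self.refs = list(v["barcode"])
        self.ids = list(v["vector_id"])
        self.exact = dict(zip(self.refs, self.ids))
        self._near1: dict[str, str] | None = None

    def _neighbors1(self) -> dict[str, str]:
        # all Hamming-1 neighbors; collisions marked ambiguous
        if self._near1 is None:
            near: dict[str, str] = {}
            for ref, vid in zip(self.refs, self.ids):
                for pos in range(len(ref)):
                    for base in "ACGT":
                        if base == ref[pos]:
                            continue
                        mut = ref[:pos] + base + ref[pos + 1:]
                        near[mut] = AMBIGUOUS if mut in near else vid
            self._near1 = near
        return self._near1

    def match(self, barcode: str) -> str | None:
        """vector_id, AMBIGUOUS, or None (nothing within max_edit)."""
        hit = self.exact.get(barcode)
        if hit is not None:
            return hit
        if self.max_edit == 0:
            return None
        if len(barcode) == self.bc_len:
            hit = self._neighbors1().get(barcode)
            if hit is not None:
                return hit
            if self.max_edit == 1:
                return None
        return self._scan(barcode)

    def _scan(self, barcode: str) -> str | None:
        best_d = self.max_edit + 1
        best: str | None = None
        tie = False
        for ref, vid in zip(self.refs, self.ids):
            d = edlib.align(barcode, ref, mode="NW", task="distance", k=self.max_edit)["editDistance"]
            if d < 0:
                continue
            if d < best_d:
                best, best_d, tie = vid, d, False
            elif d == best_d:
                tie = True
        if best is None:
            return None
        return AMBIGUOUS if tie else best


def match_barcode(seq: str, library: LibraryDef, max_edit: int = 2, max_anchor_mm: int = 1) -> str | None:
    """Match one read (or bare barcode) against the library.

    If the sequence contains the read flanks, the barcode is extracted
    between them first; otherwise it is treated as a bare barcode. Returns
    vector_id, readproc.AMBIGUOUS, or None.
    """
    region = extract_between(seq, FLANK5, FLANK3, max_anchor_mm)
    if region is None:
        region = seq
    return BarcodeMatcher(library, max_edit).match(region)


def count_features(
    reads_per_sample: dict[str, Iterable[str]],
    library: LibraryDef,
    sheet: SampleSheet,
    level: str = "barcode",
    assignment: pd.DataFrame | None = None,
    max_edit: int = 2,
    max_anchor_mm: int = 1,
) -> tuple[CountMatrix, dict[str, dict[str, int]]]:
    """Match demultiplexed reads and tally a feature x sample count matrix.

    level='barcode' counts per vector; level='shrna' requires an assignment
    table and maps each matched barcode to its assigned shRNA. Ambiguous,
    unmatched and anchorless reads are tallied per sample, never counted.
    """
    unknown = set(reads_per_sample) - set(sheet.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)}")
    if level not in ("barcode", "shrna"):
        raise ValueError(f"level must be 'barcode' or 'shrna', got {level!r}")
    bc_to_feature: dict[str, str] | None = None
    if level == "shrna":
        if assignment is None:
            raise ValueError("level='shrna' requires an assignment table")
        ok = assignment[assignment["status"] == "assigned"]
        bc_to_feature = dict(zip(ok["barcode"], ok["shrna_id"]))

    matcher = BarcodeMatcher(library, max_edit)
    vid_to_bc = dict(zip(library.vectors["vector_id"], library.vectors["barcode"]))
    features = (
        list(library.vectors["vector_id"]) if level == "barcode" else sorted(set(bc_to_feature.values()))
    )
    feat_index = {f: i for i, f in enumerate(features)}
    mat = np.zeros((len(features), len(sheet.sample_ids)), dtype=np.int64)
    tallies: dict[str, dict[str, int]] = {}

    flank_start = SAMPLE_CODE_LEN
    bc_start = flank_start + len(FLANK5)
    bc_end = bc_start + library.barcode_length

    for col, sample in enumerate(sheet.sample_ids):
        t = Counter()
        for read in reads_per_sample.get(sample, ()):  # type: ignore[arg-type]
            t["total"] += 1
            # fast path: fixed layout with intact flanks at expected offsets
            if read[flank_start:bc_start] == FLANK5 and read[bc_end:bc_end + len(FLANK3)] == FLANK3:
                region = read[bc_start:bc_end]
            else:
                region = extract_between(read[flank_start:], FLANK5, FLANK3, max_anchor_mm)
                if region is None:
                    t["no_anchor"] += 1
                    continue
            vid = matcher.match(region)
            if vid is None:
                t["unmatched"] += 1
                continue
            if vid == AMBIGUOUS:
                t["ambiguous"] += 1
                continue
            if bc_to_feature is not None:
                feature = bc_to_feature.get(vid_to_bc[vid])
                if feature is None:
                    t["unassigned_barcode"] += 1
                    continue
            else:
                feature = vid
            mat[feat_index[feature], col] += 1
            t["counted"] += 1
        tallies[sample] = dict(t)

    counts = pd.DataFrame(mat, index=pd.Index(features, name="feature"), columns=sheet.sample_ids)
    if level == "barcode":
        feat_ann = library.feature_table().loc[features]
    else:
        feat_ann = (
            library.vectors.drop_duplicates("shrna_id").set_index("shrna_id")[["gene", "is_calibrator"]].loc[features]
        )
    return CountMatrix(counts, sheet.design(), feat_ann, level=level), tallies


def build_assignment(
    reads: Iterable[str],
    library: LibraryDef,
    min_reads: int = 3,
    min_purity: float = 0.8,
    max_anchor_mm: int = 1,
) -> tuple[pd.DataFrame, dict[str, float | int]]:
    """Barcode -> shRNA dictionary from amplicon reads by majority vote.

    Per observed barcode the majority guide is chosen; status is
    'low_support' below min_reads, 'ambiguous' on a tied vote or purity
    below min_purity, else 'assigned'. Returns the table plus a recovery
    report (fraction of library genes with >= 1 assigned barcode).

    Barcodes are semi-random and unknown before this run, so sequencing
    errors necessarily create spurious low-support barcodes that the
    min_reads threshold removes. The guide sequences, in contrast, come
    from a known collection, so observed guides are error-corrected against
    it (unique Hamming-1 neighbor) before voting.
    """
    guide_to_shrna = library.guide_to_shrna()
    shrna_gene = dict(zip(library.vectors["shrna_id"], library.vectors["gene"]))

    known_guides = set(guide_to_shrna)
    correct_cache: dict[str, str] = {}

    def correct_guide(g: str) -> str:
        if g in known_guides:
            return g
        hit = correct_cache.get(g)
        if hit is not None:
            return hit
        best = [k for k in known_guides if len(k) == len(g) and hamming(g, k) <= 1]
        out = best[0] if len(best) == 1 else g
        correct_cache[g] = out
        return out

    votes: dict[str, Counter] = {}
    n_total = 0
    n_parsed = 0
    for read in reads:
        n_total += 1
        bc = extract_between(read, BC_ANCHOR_L, BC_ANCHOR_R, max_anchor_mm)
        guide = extract_between(read, GUIDE_ANCHOR_L, GUIDE_ANCHOR_R, max_anchor_mm)
        if bc is None or guide is None:
            continue
        n_parsed += 1
        votes.setdefault(bc, Counter())[correct_guide(guide)] += 1

    rows = []
    for bc, counter in sorted(votes.items()):
        support = sum(counter.values())
        ranked = counter.most_common()
        top_guide, top_n = ranked[0]
        tie = len(ranked) > 1 and ranked[1][1] == top_n
        purity = top_n / support
        shrna = guide_to_shrna.get(top_guide, "")
        if support < min_reads:
            status = "low_support"
        elif tie or purity < min_purity or shrna == "":
            status = "ambiguous"
        else:
            status = "assigned"
        rows.append((bc, shrna, shrna_gene.get(shrna, ""), support, purity, status))

    table = pd.DataFrame(rows, columns=["barcode", "shrna_id", "gene", "support", "purity", "status"])
    genes = set(library.genes)
    recovered = set(table.loc[table["status"] == "assigned", "gene"]) & genes
    report = {
        "reads_total": n_total,
        "reads_parsed": n_parsed,
        "barcodes_observed": len(table),
        "barcodes_assigned": int((table["status"] == "assigned").sum()),
        "gene_recovery": len(recovered) / len(genes) if genes else float("nan"),
    }
    if n_parsed == 0:
        import warnings

        warnings.warn("no parseable assignment read; assignment table is empty")
    return table, report


def write_tally(path: str, tally: dict) -> None:
    with open(path, "w") as fh:
        json.dump(tally, fh, indent=2, sort_keys=True)
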