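"""Synthetic screens with known ground truth.

Emulates a pooled sensor-effector reporter screen: a library of genes with
5-6 shRNAs each, every shRNA tagged by a unique 35-nt vector barcode whose
expression reads out reporter (sensor) activity. Silenced (TTX) samples
measure vector abundance; stimulated (BIC) samples measure abundance times
the sensor induction (about 21-fold) modulated per shRNA by its knockdown
effect 2**delta. Knockdown of a positive regulator of the pathway lowers
stimulated activity (delta < 0), a negative regulator raises it.

Counts are negative-binomial (variance mu + alpha*mu**2) around those
expectations; reads are emitted with a fixed layout
``[12-nt sample code][5' flank][barcode][3' flank]`` plus per-base
substitution errors, so the read-processing stages can be tested by exact
round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .containers import (
    COND_BIC,
    COND_REF,
    COND_TTX,
    CountMatrix,
    make_design,
    screen_design,
    stage_rng,
)
from .fastq import write_fastq

# Fixed read-layout constants of this artifact. Anchored extraction only
# needs them to be distinctive; they are not a real primer scheme.
FLANK5 = "CCCGAGGC"
FLANK3 = "AAGCGGCC"

# Assignment amplicon layout (total 345 nt with a 35-nt barcode and a
# 21-nt guide, keeping barcode and shRNA within one read).
A_PREFIX = "AGGTAACCGCGCAGTGAGGTTACCGTGGCT"
BC_ANCHOR_L = "CAGAAATTTA"
BC_ANCHOR_R = "GGGTTAACTT"
A_MID = (
    "GCGTTCCGTGGTTCCTACCCGGGGTGTGAGAACTGATATCCCAATAATGTCTGATCCAACTGCCGCACTG"
    "GCTTTAAGGGCGGGGTATGCAGGACGGGTGTATATCAGGAGGGCATTTTGGAGATCGTTTTATGCTCCGA"
    "CGTCAATGGC"
)
GUIDE_ANCHOR_L = "GATAGCCTAT"
GUIDE_ANCHOR_R = "TCGTCCATGC"
A_TAIL = "CAAAATTATACCGCTTATCTTGGCACCTGCTGCATAAGCCTGTCTTCTCTAACCAACTGATTAGTTTCC"

SAMPLE_CODE_LEN = 12
BASES = np.array(list("ACGT"))

CLASS_POS = "positive_regulator"
CLASS_NEG = "negative_regulator"
CLASS_NULL = "null"


@dataclass
class SimConfig:
    """Generative parameters of a synthetic screen.

    Defaults are the reference study conditions: 200 genes with 5-6 shRNAs
    each, 10% positive regulators (delta ~ N(-1, 0.3) in log2 units), 5%
    negative regulators (delta ~ N(+0.8, 0.3)), 21-fold sensor induction,
    negative-binomial dispersion 0.05, 2e6 baseline reads per sample,
    3 replicates per condition, 0.5% per-base substitution error.
    """

    n_genes: int = 200
    shrnas_per_gene: tuple[int, ...] = (5, 6)
    barcodes_per_shrna: int = 1
    barcode_length: int = 35
    guide_length: int = 21
    frac_pos: float = 0.10
    frac_neg: float = 0.05
    effect_mean_pos: float = -1.0
    effect_sd_pos: float = 0.3
    effect_mean_neg: float = 0.8
    effect_sd_neg: float = 0.3
    induction_fold: float = 21.0
    abundance_sigma: float = 1.5
    replicate_sigma: float = 0.1
    dispersion: float = 0.05
    depth: int = 2_000_000
    n_replicates: int = 3
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_pos", "frac_neg", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_pos + self.frac_neg > 1.0:
            raise ValueError("frac_pos + frac_neg must be <= 1")
        if self.induction_fold <= 0:
            raise ValueError("induction_fold must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_genes < 1 or not self.shrnas_per_gene:
            raise ValueError("need at least one gene and one shRNA count")
        self.shrnas_per_gene = tuple(sorted(set(int(k) for k in self.shrnas_per_gene)))


@dataclass
class LibraryDef:
    """The vector universe: barcode <-> shRNA <-> gene mapping.

    ``vectors`` columns: vector_id, barcode, shrna_id, guide, gene,
    is_calibrator. Calibrators have an empty gene.
    """

    vectors: pd.DataFrame
    barcode_length: int = 35

    def __post_init__(self) -> None:
        if self.vectors["barcode"].duplicated().any():
            raise ValueError("barcodes must be unique within a library")
        g = self.vectors.loc[self.vectors["guide"] != "", ["guide", "shrna_id"]].drop_duplicates()
        if g["guide"].duplicated().any():
            raise ValueError("a guide must identify a unique shRNA")

    @property
    def genes(self) -> list[str]:
        g = self.vectors.loc[~self.vectors["is_calibrator"], "gene"]
        return sorted(g.unique())

    def barcode_to_vector(self) -> dict[str, str]:
        return dict(zip(self.vectors["barcode"], self.vectors["vector_id"]))

    def guide_to_shrna(self) -> dict[str, str]:
        sub = self.vectors[self.vectors["guide"] != ""]
        return dict(zip(sub["guide"], sub["shrna_id"]))

    def feature_table(self) -> pd.DataFrame:
        return (
            self.vectors.set_index("vector_id")[["shrna_id", "gene", "is_calibrator"]]
        )

    def to_tsv(self, path: str) -> None:
        self.vectors.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "LibraryDef":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"guide": str, "gene": str})
        df["is_calibrator"] = df["is_calibrator"].astype(bool)
        return cls(df, barcode_length=len(df["barcode"].iloc[0]) if len(df) else 35)


def _random_seqs(rng: np.random.Generator, n: int, length: int, taken: set[str], what: str) -> list[str]:
    """Draw n distinct random sequences not present in `taken` (bounded retries)."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 100:
            raise RuntimeError(f"could not draw {n} distinct {what} sequences after {attempts} attempts")
        s = "".join(BASES[rng.integers(0, 4, length)])
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def build_library(config: SimConfig) -> tuple[LibraryDef, pd.DataFrame]:
    """Draw a library and its ground-truth effect table.

    Returns (LibraryDef, EffectTable). The effect table has one row per
    shRNA: gene, class (positive_regulator / negative_regulator / null) and
    delta, the log2 shift of stimulated activity. All shRNAs of a gene share
    the gene's class; magnitudes vary per shRNA. Deterministic given
    ``config.seed``.
    """
    rng = stage_rng(config.seed, "library")
    genes = [f"Gene{i:04d}" for i in range(config.n_genes)]

    n_pos = int(round(config.frac_pos * config.n_genes))
    n_neg = int(round(config.frac_neg * config.n_genes))
    classes = np.array([CLASS_POS] * n_pos + [CLASS_NEG] * n_neg + [CLASS_NULL] * (config.n_genes - n_pos - n_neg))
    rng.shuffle(classes)

    taken_bc: set[str] = set()
    taken_guide: set[str] = set()
    vec_rows = []
    eff_rows = []
    for gene, klass in zip(genes, classes):
        k = int(rng.choice(config.shrnas_per_gene))
        guides = _random_seqs(rng, k, config.guide_length, taken_guide, "guide")
        for j in range(k):
            shrna = f"{gene}_sh{j + 1}"
            if klass == CLASS_POS:
                delta = rng.normal(config.effect_mean_pos, config.effect_sd_pos)
            elif klass == CLASS_NEG:
                delta = rng.normal(config.effect_mean_neg, config.effect_sd_neg)
            else:
                delta = 0.0
            eff_rows.append((shrna, gene, klass, delta))
            barcodes = _random_seqs(rng, config.barcodes_per_shrna, config.barcode_length, taken_bc, "barcode")
            for b, bc in enumerate(barcodes):
                vid = shrna if config.barcodes_per_shrna == 1 else f"{shrna}_bc{b + 1}"
                vec_rows.append((vid, bc, shrna, guides[j], gene, False))

    vectors = pd.DataFrame(vec_rows, columns=["vector_id", "barcode", "shrna_id", "guide", "gene", "is_calibrator"])
    effects = pd.DataFrame(eff_rows, columns=["shrna_id", "gene", "class", "delta"])
    return LibraryDef(vectors, config.barcode_length), effects


def simulate_counts(
    library: LibraryDef,
    effects: pd.DataFrame,
    config: SimConfig,
    design: pd.DataFrame | None = None,
) -> CountMatrix:
    """Draw a count matrix for the given design (default: n_replicates TTX
    vs n_replicates BIC).

    Expected expression of vector i in sample j is ``a_i * r_j`` for
    silenced samples and ``a_i * r_j * F * 2**delta_i`` for stimulated
    ones, with a_i log-normal vector abundance shared across samples and
    r_j per-replicate multiplicative noise. Means are scaled so a
    baseline-activity column totals ``depth`` reads; stimulated columns
    therefore total about ``F * depth``, mirroring the induction of
    barcode RNA (the analysis chain removes this via total-read
    normalization). Counts are NB with variance mu + dispersion * mu**2.
    """
    if len(library.vectors) == 0:
        raise ValueError("empty library")
    if design is None:
        design = screen_design(config.n_replicates, config.n_replicates)

    rng = stage_rng(config.seed, "counts")
    v = library.vectors
    delta = v["shrna_id"].map(effects.set_index("shrna_id")["delta"]).fillna(0.0).to_numpy()
    a = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(v))
    w = a / a.sum()

    cols = {}
    for sample_id, row in design.iterrows():
        r_j = rng.lognormal(mean=0.0, sigma=config.replicate_sigma)
        mean = config.depth * w * r_j
        if row["condition"] == COND_BIC:
            mean = mean * config.induction_fold * np.power(2.0, delta)
        cols[sample_id] = _nb_draw(rng, mean, config.dispersion)

    counts = pd.DataFrame(cols, index=v["vector_id"].to_numpy())
    counts.index.name = "feature"
    return CountMatrix(counts, design, library.feature_table(), level="barcode")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2 via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def make_sample_codes(n: int, rng: np.random.Generator, length: int = SAMPLE_CODE_LEN, min_dist: int = 5) -> list[str]:
    """Random sample codes with pairwise Hamming distance >= min_dist."""
    codes: list[str] = []
    attempts = 0
    while len(codes) < n:
        attempts += 1
        if attempts > 200 * n + 100:
            raise RuntimeError("could not draw well-separated sample codes")
        c = "".join(BASES[rng.integers(0, 4, length)])
        if all(sum(a != b for a, b in zip(c, prev)) >= min_dist for prev in codes):
            codes.append(c)
    return codes


def make_sample_sheet(design: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Sample sheet rows (sample_id, code, condition, replicate, timepoint)."""
    rng = stage_rng(seed, "codes")
    codes = make_sample_codes(len(design), rng)
    sheet = design.reset_index().copy()
    sheet.insert(1, "code", codes)
    return sheet


def _mutate_reads(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitutions at error_rate; loops only over reads that
    actually carry an error (rare at realistic rates)."""
    if error_rate <= 0 or len(reads) == 0:
        return reads
    length = len(reads[0])
    n_err = rng.binomial(length, error_rate, size=len(reads))
    hit = np.nonzero(n_err)[0]
    for i in hit:
        seq = list(reads[i])
        for pos in rng.choice(length, size=n_err[i], replace=False):
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq[pos] = choices[rng.integers(0, 3)]
        reads[i] = "".join(seq)
    return reads


def _screen_read_stream(
    counts: CountMatrix,
    library: LibraryDef,
    sheet: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> Iterator[str]:
    code_of = dict(zip(sheet["sample_id"], sheet["code"]))
    barcodes = library.vectors.set_index("vector_id")["barcode"]
    bc = barcodes.loc[counts.counts.index].to_numpy()
    for sample in counts.samples:
        if sample not in code_of:
            raise ValueError(f"sample {sample!r} has no code in the sample sheet")
        code = code_of[sample]
        n = counts.counts[sample].to_numpy()
        nz = np.nonzero(n)[0]
        templates = np.array([f"{code}{FLANK5}{b}{FLANK3}" for b in bc[nz]], dtype=object)
        reads = np.repeat(templates, n[nz])
        reads = _mutate_reads(reads, config.error_rate, rng)
        yield from reads


def emit_screen_reads(
    counts: CountMatrix,
    library: LibraryDef,
    sheet: pd.DataFrame,
    config: SimConfig,
    path: str,
) -> int:
    """Write one read per counted molecule to FASTQ; returns reads written.

    Read layout: [12-nt sample code][5' flank][barcode][3' flank], with
    substitution errors at ``config.error_rate``. The number of reads per
    (sample, barcode) equals the count-matrix entry exactly.
    """
    rng = stage_rng(config.seed, "screen_reads")
    return write_fastq(path, _screen_read_stream(counts, library, sheet, config, rng))


def assignment_amplicon(barcode: str, guide: str) -> str:
    """The 345-nt amplicon carrying both barcode and guide."""
    return (
        A_PREFIX + BC_ANCHOR_L + barcode + BC_ANCHOR_R + A_MID
        + GUIDE_ANCHOR_L + guide + GUIDE_ANCHOR_R + A_TAIL
    )


def emit_assignment_reads(
    library: LibraryDef,
    depth_per_vector: int,
    config: SimConfig,
    path: str,
) -> int:
    """Per vector, depth_per_vector amplicon reads (barcode + guide in one
    read, anchored), with substitution errors at config.error_rate."""
    if depth_per_vector < 1:
        raise ValueError("depth_per_vector must be >= 1")
    rng = stage_rng(config.seed, "assignment_reads")

    def stream() -> Iterator[str]:
        for _, row in library.vectors.iterrows():
            reads = np.repeat(
                np.array([assignment_amplicon(row["barcode"], row["guide"])], dtype=object),
                depth_per_vector,
            )
            yield from _mutate_reads(reads, config.error_rate, rng)

    return write_fastq(path, stream())


# ---------------------------------------------------------------------------
# cisProfiler panel simulation


@dataclass
class SensorSpec:
    """A planted sensor response: log2 fold change vs the untreated
    reference under TTX and under BIC at 2/4/8 h. Calibrators are flat."""

    name: str
    is_calibrator: bool = False
    ttx: float = 0.0
    bic: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def dynamic_range(self) -> float:
        return self.bic[1] - self.ttx


def default_panel(n_sensors: int = 70, n_calibrators: int = 3, seed: int = 0) -> list[SensorSpec]:
    """A panel emulating a ~70-reporter profiling library.

    The activity sensor 'SARE' is planted with the largest dynamic range
    (log2(21) between BIC 4 h and TTX); other responsive sensors get
    sustained / amplified / transient curves; the rest are flat. Includes
    promoter-only calibrators.
    """
    rng = stage_rng(seed, "panel")
    panel = [SensorSpec(f"MLPonly_{i + 1}", is_calibrator=True) for i in range(n_calibrators)]
    sare_range = float(np.log2(21.0))
    panel.append(SensorSpec("SARE", ttx=-1.4, bic=(2.4, sare_range - 1.4, 2.7)))

    named = ["FOS", "EGR1", "NPAS4", "BDNFpI", "ARC", "JUNB"]
    n_rest = n_sensors - len(panel) - 0
    kinds = rng.choice(["sustained", "amplified", "transient", "flat"], size=n_rest, p=[0.2, 0.15, 0.15, 0.5])
    for i, kind in enumerate(kinds):
        name = named[i] if i < len(named) and kind != "flat" else f"SENSOR{i + 1:02d}"
        if kind == "flat":
            panel.append(SensorSpec(name, ttx=float(rng.normal(0, 0.1)), bic=tuple(rng.normal(0, 0.1, 3))))
            continue
        # peak + |ttx| < log2(21): SARE keeps the largest dynamic range
        peak = float(rng.uniform(1.2, 3.0))
        ttx = float(rng.uniform(-1.0, -0.2))
        if kind == "amplified":
            bic = (0.5 * peak, 0.8 * peak, peak)
        elif kind == "transient":
            bic = (peak, 0.8 * peak, float(rng.uniform(0.1, 0.4)) * peak)
        else:  # sustained
            bic = (0.8 * peak, peak, float(rng.uniform(0.6, 0.95)) * peak)
        panel.append(SensorSpec(name, ttx=ttx, bic=bic))
    return panel


def profiler_design(n_replicates: int = 2) -> pd.DataFrame:
    """Untreated reference, TTX, and BIC at 2/4/8 h, in duplicates."""
    rows = []
    for cond, tp in [(COND_REF, None), (COND_TTX, None), (COND_BIC, 2.0), (COND_BIC, 4.0), (COND_BIC, 8.0)]:
        label = cond if tp is None else f"{cond}{int(tp)}h"
        for r in range(n_replicates):
            rows.append((f"{label}_r{r + 1}", cond, f"r{r + 1}", tp))
    return make_design(rows)


def simulate_cisprofiler(
    config: SimConfig,
    panel: Sequence[SensorSpec],
    barcodes_per_sensor: int = 3,
    n_replicates: int = 2,
) -> tuple[LibraryDef, CountMatrix]:
    """Simulate a profiling run: sensors x {reference, TTX, BIC 2/4/8 h} in
    duplicates, three barcode replicates per sensor, planted response
    curves, calibrators flat. Returns the panel library (49-nt barcodes)
    and the count matrix."""
    if not panel:
        raise ValueError("empty panel")
    if not any(s.is_calibrator for s in panel):
        raise ValueError("panel must include at least one calibrator sensor")

    rng = stage_rng(config.seed, "profiler")
    taken: set[str] = set()
    rows = []
    for s in panel:
        for b in range(barcodes_per_sensor):
            bc = _random_seqs(rng, 1, 49, taken, "barcode")[0]
            rows.append((f"{s.name}_bc{b + 1}", bc, f"{s.name}_bc{b + 1}", "", s.name, s.is_calibrator))
    vectors = pd.DataFrame(rows, columns=["vector_id", "barcode", "shrna_id", "guide", "gene", "is_calibrator"])
    library = LibraryDef(vectors, barcode_length=49)

    design = profiler_design(n_replicates)
    resp = {}
    for s in panel:
        resp[(s.name, COND_REF, None)] = 0.0
        resp[(s.name, COND_TTX, None)] = s.ttx
        for tp, fc in zip((2.0, 4.0, 8.0), s.bic):
            resp[(s.name, COND_BIC, tp)] = fc

    a = rng.lognormal(0.0, config.abundance_sigma, size=len(vectors))
    w = a / a.sum()
    sensor = vectors["gene"].to_numpy()
    cols = {}
    for sample_id, row in design.iterrows():
        r_j = rng.lognormal(0.0, config.replicate_sigma)
        tp = row["timepoint"]
        fc = np.array([resp[(s, row["condition"], None if pd.isna(tp) else float(tp))] for s in sensor])
        mean = config.depth * w * r_j * np.power(2.0, fc)
        cols[sample_id] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(cols, index=vectors["vector_id"].to_numpy())
    counts.index.name = "feature"
    return library, CountMatrix(counts, design, library.feature_table(), level="barcode")


def effects_to_tsv(effects: pd.DataFrame, path: str) -> None:
    effects.to_csv(path, sep="\t", index=False)


def effects_from_tsv(path: str) -> pd.DataFrame:
    # keep_default_na: the class label "null" must stay a string
    return pd.read_csv(path, sep="\t", keep_default_na=False)
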