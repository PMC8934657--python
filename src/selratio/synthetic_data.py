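"""Desk-scale synthetic genomes with the statistical structure the analysis assumes.

Each simulated chromosome is a left-to-right layout of loci; a locus is an
upstream ancestral repeat, spacer DNA (sometimes carrying a decoy repeat
that the Yang criteria must reject), the feature, more spacer, and a
downstream ancestral repeat. Sequence pairs (human/mouse, optionally plus a
rhesus-like third species on a star tree) diverge under a GTR substitution
process: ARs and spacers at the locus's neutral rate, the feature at that
rate times a per-locus multiplier (1 = neutral, < 0.5 negatively selected,
> 2 rapidly evolving). The neutral rate may vary smoothly along the
chromosome to emulate the mega-base-scale linkage of mutation rates that
motivates a local null model. Indels are modelled as deletions in the
non-reference lineages, purely to exercise de-gapping; ground-truth
distances refer to the substitution process only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evo_distance import BASES, gtr_rate_matrix, transition_probs
from .genomic_io import (
    AlignmentBlock,
    GenomicInterval,
    MafRow,
    write_bed_intervals,
    write_maf_blocks,
)

# Human-like composition with a transition/transversion bias.
DEFAULT_BASE_FREQS = np.array([0.295, 0.205, 0.205, 0.295])
DEFAULT_EXCHANGEABILITIES = np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0])  # AC AG AT CG CT GT

REPEAT_EXTRA_COLUMNS = {
    6: ("repeat_class", "str"),
    7: ("family", "str"),
    8: ("divergence", "float"),
    9: ("lineage", "str"),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    n_loci: int = 200
    feature_length: int | tuple[int, int] = 200
    # RepeatMasker-like spread of fragment lengths, so sampled-AR covariate
    # cells overlap those of the features
    ar_length: int | tuple[int, int] = (120, 800)
    spacing: tuple[int, int] = (100, 300)
    neutral_rate: float = 0.4  # substitutions/site between the species pair
    rate_profile: str = "flat"  # "flat" or "sine"
    rate_amplitude: float = 0.0  # relative amplitude for the "sine" profile
    rate_period: int = 50  # profile period, in loci
    feature_rate_multipliers: list[float] | float = 1.0
    base_freqs: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_FREQS.copy())
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXCHANGEABILITIES.copy()
    )
    indel_rate: float = 0.005  # per-site deletion start probability, non-ref lineages
    indel_mean_length: float = 3.0
    include_third_species: bool = True
    decoy_fraction: float = 0.25  # loci carrying a Yang-rejectable decoy repeat
    chrom: str = "chrSim"
    species: tuple[str, str, str] = ("human", "rhesus", "mouse")
    max_block_columns: int = 600
    seed: int = 0

    def multiplier_for(self, locus: int) -> float:
        if isinstance(self.feature_rate_multipliers, (int, float)):
            return float(self.feature_rate_multipliers)
        return float(self.feature_rate_multipliers[locus % len(self.feature_rate_multipliers)])

    def neutral_rate_at(self, locus: int) -> float:
        if self.rate_profile == "flat" or self.rate_amplitude == 0:
            return self.neutral_rate
        phase = 2 * math.pi * locus / self.rate_period
        return self.neutral_rate * (1.0 + self.rate_amplitude * math.sin(phase))


@dataclass
class SimResult:
    maf_path: Path
    feature_bed: Path
    repeat_bed: Path
    truth_path: Path
    truth: pd.DataFrame
    degapped_feature_columns: dict[str, int]


def _expected_label(multiplier: float) -> str:
    if multiplier < 0.5:
        return "negative"
    if multiplier > 2.0:
        return "rapid"
    return "neutral"


def _draw_length(spec, rng) -> int:
    if isinstance(spec, (tuple, list)):
        return int(rng.integers(spec[0], spec[1] + 1))
    return int(spec)


def simulate_pair(
    length: int,
    distance: float,
    base_freqs: np.ndarray = DEFAULT_BASE_FREQS,
    exchangeabilities: np.ndarray = DEFAULT_EXCHANGEABILITIES,
    seed: int | np.random.Generator = 0,
    indel_rate: float = 0.0,
    indel_mean_length: float = 3.0,
) -> tuple[str, str]:
    """Sample an aligned sequence pair at the given GTR distance.

    The first sequence is drawn from the stationary distribution and the
    second evolved from it through exp(Q d) — valid for any split of the
    path into two branches because the process is reversible. With
    ``indel_rate`` > 0, deletions (gap runs of geometric length) are placed
    in the second sequence, producing a gapped pairwise alignment.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = _sample_stationary(length, base_freqs, rng)
    der = _evolve(anc, distance, base_freqs, exchangeabilities, rng)
    s1 = _to_str(anc)
    s2 = _to_str(der)
    if indel_rate > 0:
        s2 = _apply_deletions(s2, indel_rate, indel_mean_length, rng)
    return s1, s2


def _sample_stationary(length, base_freqs, rng):
    return rng.choice(4, size=length, p=np.asarray(base_freqs) / np.sum(base_freqs))


def _evolve(seq_idx: np.ndarray, distance: float, base_freqs, exchangeabilities, rng):
    if distance == 0:
        return seq_idx.copy()
    pi = np.asarray(base_freqs, dtype=float)
    Q = gtr_rate_matrix(pi, exchangeabilities)
    P = transition_probs(Q, pi, distance)
    P = P / P.sum(axis=1, keepdims=True)
    out = np.empty_like(seq_idx)
    u = rng.random(len(seq_idx))
    cdf = np.cumsum(P, axis=1)
    for b in range(4):
        mask = seq_idx == b
        out[mask] = np.searchsorted(cdf[b], u[mask], side="right")
    return np.clip(out, 0, 3)


_BASE_ARR = np.frombuffer("ACGT".encode(), dtype="S1")


def _to_str(idx: np.ndarray) -> str:
    return _BASE_ARR[idx].tobytes().decode()


def _apply_deletions(seq: str, rate: float, mean_len: float, rng) -> str:
    arr = np.array(list(seq))
    n = len(arr)
    starts = np.nonzero(rng.random(n) < rate)[0]
    p_geom = min(1.0, 1.0 / mean_len)
    for s in starts:
        length = int(rng.geometric(p_geom))
        arr[s : s + length] = "-"
    return "".join(arr)


class _GenomeBuilder:
    """Accumulates aligned segments and emits MAF blocks + coordinates."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.ref_pos = 0
        self.other_pos = {sp: 0 for sp in self._species()}
        self.columns: list[dict] = []  # queued aligned segments

    def _species(self):
        ref, third, other = self.cfg.species
        if self.cfg.include_third_species:
            return [ref, third, other]
        return [ref, other]

    def add_segment(self, seqs: dict[str, str]) -> tuple[int, int]:
        """Queue a gap-containing aligned segment; returns its ref interval."""
        width = len(next(iter(seqs.values())))
        assert all(len(s) == width for s in seqs.values())
        ref_name = self.cfg.species[0]
        ref_len = sum(1 for c in seqs[ref_name] if c != "-")
        start = self.ref_pos
        self.columns.append(seqs)
        self.ref_pos += ref_len
        return start, self.ref_pos

    def to_blocks(self) -> list[AlignmentBlock]:
        species = self._species()
        full = {sp: "".join(seg[sp] for seg in self.columns) for sp in species}
        width = len(full[species[0]])
        src_size = {sp: sum(1 for c in full[sp] if c != "-") for sp in species}
        blocks = []
        pos = {sp: 0 for sp in species}
        ref = self.cfg.species[0]
        step = self.cfg.max_block_columns
        for j0 in range(0, width, step):
            j1 = min(j0 + step, width)
            rows = []
            for sp in species:
                text = full[sp][j0:j1]
                size = sum(1 for c in text if c != "-")
                chrom = self.cfg.chrom if sp == ref else f"{self.cfg.chrom}_{sp}"
                rows.append(
                    MafRow(
                        species=sp, chrom=chrom, start=pos[sp], size=size,
                        strand="+", src_size=src_size[sp], text=text,
                    )
                )
                pos[sp] += size
            block = AlignmentBlock(rows=rows, score=0.0)
            if rows[0].size > 0:  # skip blocks with no reference bases
                blocks.append(block)
        return blocks


def _simulate_aligned(cfg, rng, length, distance):
    """Aligned segment for 2 or 3 species at a given ref-partner distance.

    Third species sits on a star tree: branch lengths are fractions of the
    pair distance (reference 0.2 d, partner 0.8 d, third 0.25 d), so the
    reference-partner path length is exactly ``distance``.
    """
    pi, ex = cfg.base_freqs, cfg.exchangeabilities
    anc = _sample_stationary(length, pi, rng)
    ref_idx = _evolve(anc, 0.2 * distance, pi, ex, rng)
    other_idx = _evolve(anc, 0.8 * distance, pi, ex, rng)
    seqs = {cfg.species[0]: _to_str(ref_idx), cfg.species[2]: _to_str(other_idx)}
    if cfg.include_third_species:
        third_idx = _evolve(anc, 0.25 * distance, pi, ex, rng)
        seqs[cfg.species[1]] = _to_str(third_idx)
    if cfg.indel_rate > 0:
        for sp in list(seqs):
            if sp == cfg.species[0]:
                continue
            seqs[sp] = _apply_deletions(seqs[sp], cfg.indel_rate, cfg.indel_mean_length, rng)
    return seqs


def _degapped_columns(seqs: dict[str, str]) -> int:
    width = len(next(iter(seqs.values())))
    return sum(
        1 for j in range(width) if all(s[j] != "-" for s in seqs.values())
    )


def simulate_genome(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """Emit MAF + feature BED + repeat BED + ground-truth table for one genome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    builder = _GenomeBuilder(cfg)
    features: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    truth_rows = []
    degapped_cols: dict[str, int] = {}

    def spacer(lo=None, hi=None, rate=0.4):
        lo = lo if lo is not None else cfg.spacing[0]
        hi = hi if hi is not None else cfg.spacing[1]
        length = int(rng.integers(lo, hi + 1))
        builder.add_segment(_simulate_aligned(cfg, rng, length, rate))

    for locus in range(cfg.n_loci):
        rate = cfg.neutral_rate_at(locus)
        mult = cfg.multiplier_for(locus)
        ar_len_up = _draw_length(cfg.ar_length, rng)
        ar_len_down = _draw_length(cfg.ar_length, rng)
        feat_len = _draw_length(cfg.feature_length, rng)

        spacer(rate=rate)
        # upstream ancestral repeat
        seqs = _simulate_aligned(cfg, rng, ar_len_up, rate)
        start, end = builder.add_segment(seqs)
        repeats.append(_make_repeat(cfg, rng, start, end, locus, "up", decoy=False))
        spacer(rate=rate)
        # optional decoy repeat the Yang rules must reject
        if rng.random() < cfg.decoy_fraction:
            dec_len = _draw_length((150, 350), rng)
            seqs = _simulate_aligned(cfg, rng, dec_len, rate)
            dstart, dend = builder.add_segment(seqs)
            repeats.append(_make_repeat(cfg, rng, dstart, dend, locus, "decoy", decoy=True))
            spacer(rate=rate)
        # the feature itself
        seqs = _simulate_aligned(cfg, rng, feat_len, rate * mult)
        fstart, fend = builder.add_segment(seqs)
        fid = f"feat{locus:04d}"
        features.append(GenomicInterval(cfg.chrom, fstart, fend, "+", fid))
        degapped_cols[fid] = _degapped_columns(seqs)
        spacer(rate=rate)
        # downstream ancestral repeat
        seqs = _simulate_aligned(cfg, rng, ar_len_down, rate)
        start, end = builder.add_segment(seqs)
        repeats.append(_make_repeat(cfg, rng, start, end, locus, "down", decoy=False))

        truth_rows.append(
            {
                "locus": locus,
                "feature_id": fid,
                "neutral_distance": rate,
                "feature_distance": rate * mult,
                "multiplier": mult,
                "expected_label": _expected_label(mult),
            }
        )

    maf_path = out_dir / "genome.maf"
    write_maf_blocks(builder.to_blocks(), maf_path)
    feature_bed = out_dir / "features.bed"
    write_bed_intervals(features, feature_bed)
    repeat_bed = out_dir / "repeats.bed"
    write_bed_intervals(
        repeats, repeat_bed,
        extra_attrs=("repeat_class", "family", "divergence", "lineage"),
    )
    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(maf_path, feature_bed, repeat_bed, truth_path, truth, degapped_cols)


_DECOY_KINDS = [
    # (class, family, divergence, lineage) — each fails exactly one Yang rule
    ("SINE/Alu", "AluY", 30.0, "shared"),          # Alu exclusion
    ("LINE/L2", "L2a", 26.0, "primate_specific"),  # lineage rule
    ("DNA/hAT-Charlie", "MER5A", 15.0, "shared"),  # divergence <= 25
    ("LINE/L1", "L1M4", 18.0, "shared"),           # L1 divergence <= 20
]

_AR_KINDS = [
    ("LINE/L1", "L1MB7", (21.0, 40.0)),
    ("LINE/L2", "L2b", (26.0, 45.0)),
    ("SINE/MIR", "MIR3", (26.0, 45.0)),
    ("LTR/ERVL", "MLT1J", (26.0, 45.0)),
    ("DNA/hAT-Charlie", "MER20", (26.0, 45.0)),
]


def _make_repeat(cfg, rng, start, end, locus, tag, decoy):
    if decoy:
        rc, fam, div, lineage = _DECOY_KINDS[int(rng.integers(len(_DECOY_KINDS)))]
    else:
        rc, fam, (lo, hi) = _AR_KINDS[int(rng.integers(len(_AR_KINDS)))]
        div = float(np.round(rng.uniform(lo, hi), 1))
        lineage = "shared"
    name = f"rep{locus:04d}_{tag}"
    return GenomicInterval(
        cfg.chrom, start, end, "+", name,
        {"repeat_class": rc, "family": fam, "divergence": div, "lineage": lineage},
    )


def make_worked_fixtures(out_dir: str | Path, seed: int = 7) -> dict[str, Path]:
    """Deterministic tiny fixtures for unit tests.

    A two-block MAF whose blocks split a feature, a repeat table exercising
    each Yang selection rule, and a dot-bracket structure over a gapped
    alignment with a known basepair gap fraction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    maf = out_dir / "two_block.maf"
    maf.write_text(
        "##maf version=1\n"
        "a score=0.0\n"
        "s human.chrT 10 10 + 1000 ACGTACGTAC\n"
        "s rhesus.chrT 10 10 + 1000 ACGTACGAAC\n"
        "s mouse.chrT 10 9 + 1000 ACG-ACGTAG\n"
        "\n"
        "a score=0.0\n"
        "s human.chrT 20 10 + 1000 GTACGTACGT\n"
        "s rhesus.chrT 20 10 + 1000 GTACGAACGT\n"
        "s mouse.chrT 19 10 + 1000 GTACATACGT\n"
    )
    paths["maf"] = maf

    repeats = out_dir / "yang_repeats.bed"
    rows = [
        # retained: shared, non-Alu, divergence above threshold
        ("chrT", 0, 200, "keep_L2", "LINE/L2", "L2a", 26.0, "shared"),
        ("chrT", 300, 500, "keep_L1", "LINE/L1", "L1MB7", 22.0, "shared"),
        ("chrT", 600, 800, "keep_hAT", "DNA/hAT-Charlie", "MER20", 30.0, "shared"),
        # rejected, one rule each
        ("chrT", 900, 1100, "rej_alu", "SINE/Alu", "AluY", 30.0, "shared"),
        ("chrT", 1200, 1400, "rej_lineage", "LINE/L2", "L2b", 30.0, "primate_specific"),
        ("chrT", 1500, 1700, "rej_lowdiv", "DNA/hAT-Charlie", "MER5A", 24.0, "shared"),
        ("chrT", 1800, 2000, "rej_l1_lowdiv", "LINE/L1", "L1M4", 19.0, "shared"),
        ("chrT", 2100, 2300, "rej_rodent", "SINE/MIR", "MIR3", 30.0, "rodent_specific"),
    ]
    with open(repeats, "w") as fh:
        for chrom, s, e, name, rc, fam, div, lineage in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t+\t{rc}\t{fam}\t{div}\t{lineage}\n")
    paths["repeats"] = repeats

    gapped = out_dir / "gapped_structure.txt"
    # 6-column alignment, structure ((..)), gap in column 1 of mouse:
    # pair (0,5) gap-free, pair (1,4) gapped -> basepair gap fraction 0.5
    gapped.write_text(
        "structure\t((..))\n"
        "human\tGGAACC\n"
        "rhesus\tGGAACC\n"
        "mouse\tG-AACC\n"
    )
    paths["structure"] = gapped
    return paths
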