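"""End-to-end orchestration: read → extract → de-gap → filter → neutral
model → distances → SR → FDR → classify → report."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment_ops, genomic_io, neutral_model, selection_fdr
from .alignment_ops import FilterConfig, UnanchoredError
from .evo_distance import SaturationError, pair_distance
from .genomic_io import GenomicInterval
from .neutral_model import AncestralRepeat, ArPositionIndex, NoNeutralModelError
from .selection_fdr import FdrBinScheme, SelectionResult, UndefinedRatioError
from .synthetic_data import REPEAT_EXTRA_COLUMNS

logger = logging.getLogger("selratio")


@dataclass
class FdrConfig:
    n_ars: int = 120_000
    n_samplings: int = 10
    min_ar_len: int = 80
    with_replacement: bool = False


@dataclass
class RunConfig:
    maf: str = ""
    features: str = ""
    repeats: str = ""
    out_dir: str | None = None
    species: tuple[str, str, str] = ("human", "rhesus", "mouse")
    distance_pair: tuple[str, str] = ("human", "mouse")
    filters: FilterConfig = field(default_factory=FilterConfig)
    flank: int = 500
    borrow: bool = True
    legacy_null: bool = False
    min_sites: int = 50
    fdr: FdrConfig = field(default_factory=FdrConfig)
    thresholds: dict = field(default_factory=dict)
    mode: str = "denovo"
    compute_fdr: bool = True
    repeat_columns: dict = field(default_factory=lambda: dict(REPEAT_EXTRA_COLUMNS))
    seed: int = 0

    def __post_init__(self):
        if len(set(self.species)) != 3:
            raise ValueError("species triple must contain 3 distinct names")
        if not set(self.distance_pair) <= set(self.species):
            raise ValueError("distance pair must be a subset of the species triple")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filters" in raw:
            raw["filters"] = FilterConfig(**raw["filters"])
        if "fdr" in raw:
            raw["fdr"] = FdrConfig(**raw["fdr"])
        for key in ("species", "distance_pair"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "repeat_columns" in raw:
            raw["repeat_columns"] = {
                int(k): tuple(v) for k, v in raw["repeat_columns"].items()
            }
        return cls(**raw)


@dataclass
class PipelineResult:
    results: list[SelectionResult]
    stage_counts: dict
    diagnostics: pd.DataFrame | None
    metadata: dict


def _species_presence(blocks, repeats, species):
    """Which species have >= 1 aligned bp over each repeat interval."""
    spans = {sp: [] for sp in species}
    for block in blocks:
        ref = block.rows[0]
        for sp in species:
            row = block.row_for(sp)
            if row is not None and row.size > 0:
                spans[sp].append((ref.chrom, ref.start, ref.start + ref.size))
    presence = {}
    for rep in repeats:
        present = set()
        for sp, sp_spans in spans.items():
            if any(c == rep.interval.chrom and s < rep.interval.end and rep.interval.start < e
                   for c, s, e in sp_spans):
                present.add(sp)
        presence[rep.ar_id] = present
    return presence


def load_ancestral_repeats(blocks, repeat_intervals, cfg: RunConfig):
    """Yang-select repeats and attach their de-gapped pairwise alignments."""
    candidates = [
        AncestralRepeat(
            interval=iv,
            family=str(iv.attributes.get("family", "")),
            repeat_class=str(iv.attributes.get("repeat_class", "")),
            divergence=iv.attributes.get("divergence"),
            lineage=str(iv.attributes.get("lineage", "")),
        )
        for iv in repeat_intervals
    ]
    presence = _species_presence(blocks, candidates, cfg.species)
    selected = neutral_model.select_ancestral_repeats(
        candidates, presence, required_species=cfg.species
    )
    pair = cfg.distance_pair
    kept = []
    for ar in selected:
        try:
            sub = alignment_ops.extract_pairwise(blocks, ar.interval, pair)
        except UnanchoredError:
            continue
        deg = alignment_ops.degap(sub)
        if deg.is_empty:
            continue
        ar.attach_alignment(deg.columns[0], deg.columns[1], deg.ref_coords)
        kept.append(ar)
    return kept


def _score_feature(feature, blocks, repeats, index, cfg, counts):
    """One feature through extract/degap/filter/distances; returns result or None."""
    pair_idx = None
    try:
        aln = alignment_ops.extract_threeway(blocks, feature, cfg.species)
    except UnanchoredError:
        counts["unanchored"] += 1
        return None
    partner = cfg.distance_pair[1]
    pair_idx = aln.species.index(partner)
    deg = alignment_ops.degap(aln, pair_index=pair_idx)
    ok, reasons = alignment_ops.feature_filters(deg, feature, repeats, cfg.filters)
    if not ok:
        for reason in reasons:
            counts[reason.split(":")[0]] = counts.get(reason.split(":")[0], 0) + 1
        return None
    result = SelectionResult(
        feature_id=deg.feature_id,
        d_f=float("nan"),
        d_ln=float("nan"),
        sr=None,
        gc=deg.gc_ref,
        degapped_len=deg.n_columns,
        si=deg.si_pairwise,
        interval=feature,
    )
    try:
        fit_f = pair_distance(deg.columns[0], deg.columns[pair_idx], cfg.min_sites)
    except (SaturationError, ValueError):
        counts["distance_failed"] += 1
        return None
    result.d_f = fit_f.distance
    try:
        if cfg.legacy_null:
            ln = neutral_model.legacy_local_neutral_1kb(feature, index)
        else:
            ln = neutral_model.build_local_neutral(
                feature, index, flank=cfg.flank, borrow=cfg.borrow
            )
    except NoNeutralModelError:
        counts["no_neutral_model"] += 1
        return None
    if cfg.borrow and not cfg.legacy_null and not ln.complete:
        counts["incomplete_null"] += 1
        return None
    fit_ln = pair_distance(ln.seq_ref, ln.seq_other, cfg.min_sites)
    result.d_ln = fit_ln.distance
    try:
        result.sr = selection_fdr.selection_ratio(result.d_f, result.d_ln)
    except UndefinedRatioError:
        counts["undefined_sr"] += 1
        result.flags.add("undefined_sr")
        return result
    return result


def _score_ar_as_feature(ar, index, cfg, cache):
    """SR of a sampled AR: own distance over its neighbours' neutral model."""
    if ar.ar_id in cache:
        return cache[ar.ar_id]
    result = None
    gc_bases = sum(1 for c in ar.seq_ref if c in "GC")
    acgt = sum(1 for c in ar.seq_ref if c in "ACGT")
    si = sum(1 for a, b in zip(ar.seq_ref, ar.seq_other) if a == b) / len(ar.seq_ref)
    try:
        fit_f = pair_distance(ar.seq_ref, ar.seq_other, cfg.min_sites)
        if cfg.legacy_null:
            ln = neutral_model.legacy_local_neutral_1kb(
                ar.interval, index, exclude_ar_id=ar.ar_id
            )
        else:
            ln = neutral_model.build_local_neutral(
                ar.interval, index, flank=cfg.flank, borrow=cfg.borrow,
                exclude_ar_id=ar.ar_id,
            )
        fit_ln = pair_distance(ln.seq_ref, ln.seq_other, cfg.min_sites)
        sr = selection_fdr.selection_ratio(fit_f.distance, fit_ln.distance)
        result = SelectionResult(
            feature_id=ar.ar_id,
            d_f=fit_f.distance,
            d_ln=fit_ln.distance,
            sr=sr,
            gc=gc_bases / acgt if acgt else float("nan"),
            degapped_len=ar.degapped_length,
            si=si,
            interval=ar.interval,
        )
    except (SaturationError, NoNeutralModelError, UndefinedRatioError, ValueError):
        result = None
    cache[ar.ar_id] = result
    return result


def ar_null_samplings(ars, index, cfg: RunConfig, n_samplings: int | None = None):
    """Score ``n_samplings`` independent AR samples as features.

    Sampling i uses seed ``cfg.seed + i``; per-AR scores are cached across
    samplings since an AR's SR does not depend on the sample it is drawn in.
    """
    n_samplings = n_samplings if n_samplings is not None else cfg.fdr.n_samplings
    cache: dict = {}
    samplings = []
    for i in range(n_samplings):
        sample, flags = selection_fdr.sample_ars(
            ars, n=cfg.fdr.n_ars, min_len=cfg.fdr.min_ar_len,
            seed=cfg.seed + i, with_replacement=cfg.fdr.with_replacement,
        )
        scored = []
        for ar in sample:
            res = _score_ar_as_feature(ar, index, cfg, cache)
            if res is not None:
                scored.append(res)
        samplings.append(scored)
    return samplings


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Full analysis; returns scored features plus stage counts and diagnostics.

    Writes ``results.tsv``, ``bin_diagnostics.tsv`` and ``run_metadata.yaml``
    under ``cfg.out_dir`` when set.
    """
    blocks = genomic_io.read_maf_blocks(cfg.maf)
    features = genomic_io.read_bed_intervals(cfg.features)
    repeat_ivs = genomic_io.read_bed_intervals(cfg.repeats, cfg.repeat_columns)
    counts: dict = {"input": len(features), "unanchored": 0, "distance_failed": 0,
                    "no_neutral_model": 0, "incomplete_null": 0, "undefined_sr": 0}
    ars = load_ancestral_repeats(blocks, repeat_ivs, cfg)
    logger.info("selected %d ancestral repeats from %d repeat records",
                len(ars), len(repeat_ivs))
    index = ArPositionIndex(ars)
    results = []
    for feature in features:
        res = _score_feature(feature, blocks, repeat_ivs, index, cfg, counts)
        if res is not None:
            results.append(res)
    counts["scored"] = sum(1 for r in results if r.sr is not None)

    scheme = FdrBinScheme.default()
    diagnostics = None
    ar_sr_summary = None
    if cfg.compute_fdr and results and ars:
        samplings = ar_null_samplings(ars, index, cfg)
        scorable = [r for r in results if r.sr is not None]
        selection_fdr.empirical_fdr(scorable, samplings, scheme)
        diagnostics = selection_fdr.bin_diagnostics(scorable, samplings, scheme)
        for r in results:
            r.label = selection_fdr.classify(r.sr, r.fdr, cfg.mode, cfg.thresholds)
        ar_srs = np.array([r.sr for sampling in samplings for r in sampling
                           if r.sr is not None])
        if len(ar_srs):
            ar_sr_summary = {
                "n_scored": int(len(ar_srs)),
                "median": float(np.median(ar_srs)),
                "q25": float(np.quantile(ar_srs, 0.25)),
                "q75": float(np.quantile(ar_srs, 0.75)),
            }
    metadata = {
        "ar_null_sr": ar_sr_summary,
        "config": _config_echo(cfg),
        "stage_counts": counts,
        "n_ancestral_repeats": len(ars),
        "sampling_seeds": [cfg.seed + i for i in range(cfg.fdr.n_samplings)],
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genomic_io.write_results(results, out / "results.tsv")
        if diagnostics is not None:
            diagnostics.to_csv(out / "bin_diagnostics.tsv", sep="\t", index=False,
                               float_format="%.6f")
        with open(out / "run_metadata.yaml", "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=True)
    return PipelineResult(results, counts, diagnostics, metadata)


def run_ar_null(cfg: RunConfig, n_samplings: int = 1) -> pd.DataFrame:
    """Score one (or more) AR samplings as features and tabulate their SRs."""
    blocks = genomic_io.read_maf_blocks(cfg.maf)
    repeat_ivs = genomic_io.read_bed_intervals(cfg.repeats, cfg.repeat_columns)
    ars = load_ancestral_repeats(blocks, repeat_ivs, cfg)
    if not ars:
        raise ValueError("no ancestral repeats available")
    index = ArPositionIndex(ars)
    samplings = ar_null_samplings(ars, index, cfg, n_samplings=n_samplings)
    rows = []
    for i, sampling in enumerate(samplings):
        for r in sampling:
            rows.append({"sampling": i, "ar_id": r.feature_id, "d_F": r.d_f,
                         "d_LN": r.d_ln, "SR": r.sr, "GC": r.gc,
                         "degapped_len": r.degapped_len, "SI": r.si})
    df = pd.DataFrame(rows)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "ar_null.tsv", sep="\t", index=False, float_format="%.6f")
        quantiles = df["SR"].quantile([0.05, 0.25, 0.5, 0.75, 0.95]).to_dict()
        with open(out / "ar_null_metadata.yaml", "w") as fh:
            yaml.safe_dump({"sr_quantiles": {str(k): float(v) for k, v in quantiles.items()},
                            "n_scored": int(len(df))}, fh)
    return df


def _config_echo(cfg: RunConfig) -> dict:
    echo = asdict(cfg)
    echo["species"] = list(cfg.species)
    echo["distance_pair"] = list(cfg.distance_pair)
    echo["repeat_columns"] = {int(k): list(v) for k, v in cfg.repeat_columns.items()}
    return echo
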