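"""Selection ratio, covariate-binned empirical FDR, and classification.

The selection ratio SR(X) = d_F(X) / d_LN(X) compares a feature's
human-mouse distance to that of its local neutral model; an ancestral
repeat's expected SR is 1. Because SR depends on the feature's G+C content
and de-gapped length, the false discovery rate of extreme SR values is
estimated empirically inside G+C x length cells: features and randomly
sampled ARs (each scored exactly like a feature) are binned by SR, and for
feature X with cell counts n (features in cell), t (of them in X's SR bin),
m (sampled ARs in cell), s (of them in X's SR bin),

    FDR(SR) = min((s/m) / (t/n), 1),

averaged over independent AR samplings. Features are then classified as
negatively selected (SR < 0.5) or rapidly evolving (SR > 2; SR > 1.5 for
curated Rfam families), requiring FDR(SR) <= 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genomic_io import GenomicInterval


class UndefinedRatioError(ZeroDivisionError):
    """d_LN is zero: the selection ratio is undefined."""


@dataclass
class SelectionResult:
    feature_id: str
    d_f: float
    d_ln: float
    sr: float | None
    gc: float
    degapped_len: int
    si: float
    fdr: float | None = None
    label: str = "unclassified"
    interval: GenomicInterval | None = None
    flags: set = field(default_factory=set)


def selection_ratio(d_f: float, d_ln: float) -> float:
    """SR = d_F / d_LN; raises when the neutral distance is zero."""
    if d_ln == 0:
        raise UndefinedRatioError("local neutral distance is zero; SR undefined")
    return d_f / d_ln


# Bin scheme -----------------------------------------------------------


@dataclass
class FdrBinScheme:
    """G+C x length x SR binning used by the empirical FDR estimator.

    All interval lists are half-open (lo, hi] except the leading closed
    intervals [0, 0.25] for G+C and [0, 0.1] for SR. Defaults: 9 G+C bins
    ([0-0.25], seven width-0.05 bins to (0.55-0.60], (0.60-1.00]),
    5 length bins ((0-100], (100-150], (150-200], (200-300], (300-500]),
    41 SR bins ([0-0.1], 39 width-0.1 bins to (3.9-4.0], (4.0-inf)).
    """

    gc_edges: np.ndarray
    len_edges: np.ndarray
    sr_edges: np.ndarray

    @classmethod
    def default(cls) -> "FdrBinScheme":
        gc = np.concatenate([[0.0, 0.25], np.arange(0.30, 0.601, 0.05), [1.0]])
        lens = np.array([0, 100, 150, 200, 300, 500], dtype=float)
        sr = np.concatenate([np.arange(0.0, 4.001, 0.1), [np.inf]])
        return cls(gc_edges=np.round(gc, 10), len_edges=lens, sr_edges=np.round(sr, 10))

    @property
    def n_gc_bins(self) -> int:
        return len(self.gc_edges) - 1

    @property
    def n_len_bins(self) -> int:
        return len(self.len_edges) - 1

    @property
    def n_sr_bins(self) -> int:
        return len(self.sr_edges) - 1


def _bin_left_closed_first(value: float, edges: np.ndarray) -> int:
    """Index of the (lo, hi] bin containing value, with the first bin closed."""
    if value <= edges[1]:
        if value < edges[0]:
            raise ValueError(f"value {value} below first bin edge {edges[0]}")
        return 0
    # side="left" makes membership right-closed: edges[i] itself belongs to bin i-1
    idx = int(np.searchsorted(edges, value, side="left")) - 1
    return min(idx, len(edges) - 2)


def assign_bins(
    gc: float, degapped_len: int, sr: float, scheme: FdrBinScheme
) -> tuple[int, int, int, set]:
    """Map a feature's covariates and SR to (gc_bin, len_bin, sr_bin) indices.

    De-gapped lengths above the last boundary (500) overflow into the last
    length bin and are flagged ``len_overflow``.
    """
    flags: set = set()
    gc_bin = _bin_left_closed_first(gc, scheme.gc_edges)
    if degapped_len > scheme.len_edges[-1]:
        len_bin = scheme.n_len_bins - 1
        flags.add("len_overflow")
    else:
        len_bin = _bin_left_closed_first(float(degapped_len), scheme.len_edges)
    sr_bin = _bin_left_closed_first(sr, scheme.sr_edges)
    return gc_bin, len_bin, sr_bin, flags


# Empirical FDR --------------------------------------------------------


def sample_ars(ars: list, n: int = 120_000, min_len: int = 80, seed: int = 0,
               with_replacement: bool = False) -> tuple[list, set]:
    """Uniformly sample ARs of de-gapped length greater than ``min_len``.

    Sampling is without replacement when the eligible pool allows it;
    otherwise an error is raised unless ``with_replacement`` is set, in which
    case the sample is flagged. Returns (sample, flags).
    """
    eligible = [ar for ar in ars if ar.degapped_length > min_len]
    if not eligible:
        raise ValueError(f"no ancestral repeats with de-gapped length > {min_len}")
    rng = np.random.default_rng(seed)
    flags: set = set()
    if n > len(eligible):
        if not with_replacement:
            raise ValueError(
                f"requested {n} ARs but only {len(eligible)} eligible; "
                "enable replacement to oversample"
            )
        flags.add("sampled_with_replacement")
        idx = rng.integers(0, len(eligible), size=n)
    else:
        idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx], flags


def _cell_tables(results: list[SelectionResult], scheme: FdrBinScheme):
    """counts[gc, len, sr] plus per-result bin triples (None when SR absent)."""
    counts = np.zeros((scheme.n_gc_bins, scheme.n_len_bins, scheme.n_sr_bins), dtype=np.int64)
    triples = []
    for r in results:
        if r.sr is None or not np.isfinite(r.sr):
            triples.append(None)
            continue
        g, l, s, flags = assign_bins(r.gc, r.degapped_len, r.sr, scheme)
        r.flags |= flags
        counts[g, l, s] += 1
        triples.append((g, l, s))
    return counts, triples


def empirical_fdr(
    features: list[SelectionResult],
    ar_samplings: list[list[SelectionResult]],
    scheme: FdrBinScheme | None = None,
) -> None:
    """Attach the mean binned FDR(SR) over AR samplings to each feature in place.

    Within feature X's G+C x length cell: n features total, t sharing X's SR
    bin (t includes X itself), m sampled ARs total, s sharing the SR bin;
    per sampling FDR = min((s/m)/(t/n), 1), and the reported FDR is the mean
    over samplings. Cells with no sampled ARs leave FDR absent and flag the
    feature ``null_sparse``.
    """
    scheme = scheme or FdrBinScheme.default()
    feat_counts, feat_bins = _cell_tables(features, scheme)
    ar_tables = [_cell_tables(sampling, scheme)[0] for sampling in ar_samplings]
    for r, bins in zip(features, feat_bins):
        if bins is None:
            r.fdr = None
            continue
        g, l, s = bins
        n = int(feat_counts[g, l, :].sum())
        t = int(feat_counts[g, l, s])
        estimates = []
        for ar_counts in ar_tables:
            m = int(ar_counts[g, l, :].sum())
            if m == 0:
                continue
            s_ar = int(ar_counts[g, l, s])
            estimates.append(min((s_ar / m) / (t / n), 1.0))
        if estimates:
            r.fdr = float(np.mean(estimates))
        else:
            r.fdr = None
            r.flags.add("null_sparse")


def bin_diagnostics(
    features: list[SelectionResult],
    ar_samplings: list[list[SelectionResult]],
    scheme: FdrBinScheme | None = None,
):
    """Per-bin (n, t, m, s) table: m/s are totals over all samplings."""
    import pandas as pd

    scheme = scheme or FdrBinScheme.default()
    feat_counts, _ = _cell_tables(features, scheme)
    ar_counts = np.zeros_like(feat_counts)
    for sampling in ar_samplings:
        ar_counts += _cell_tables(sampling, scheme)[0]
    rows = []
    for g in range(scheme.n_gc_bins):
        for l in range(scheme.n_len_bins):
            n = int(feat_counts[g, l].sum())
            m = int(ar_counts[g, l].sum())
            if n == 0 and m == 0:
                continue
            for s in range(scheme.n_sr_bins):
                t = int(feat_counts[g, l, s])
                s_ar = int(ar_counts[g, l, s])
                if t == 0 and s_ar == 0:
                    continue
                fdr = min((s_ar / m) / (t / n), 1.0) if (m > 0 and t > 0) else math.nan
                rows.append({"gc_bin": g, "len_bin": l, "sr_bin": s,
                             "n": n, "t": t, "m": m, "s": s_ar, "fdr": fdr})
    return pd.DataFrame(rows)


# Classification -------------------------------------------------------

THRESHOLDS = {
    "negative": 0.5,
    "rapid": 2.0,
    "rapid_rfam": 1.5,
    "fdr_max": 0.2,
}


def classify(
    sr: float | None,
    fdr: float | None,
    mode: str = "denovo",
    thresholds: dict | None = None,
) -> str:
    """Label a feature negative / rapid / unclassified.

    Negative selection requires SR < 0.5; rapid sequence evolution requires
    SR > 2 (de novo structures) or SR > 1.5 (Rfam families); both require
    FDR(SR) <= 0.2. An absent SR or FDR leaves the feature unclassified.
    """
    th = dict(THRESHOLDS)
    th.update(thresholds or {})
    if sr is None or fdr is None:
        return "unclassified"
    if fdr > th["fdr_max"]:
        return "unclassified"
    if sr < th["negative"]:
        return "negative"
    rapid_cut = th["rapid_rfam"] if mode == "rfam" else th["rapid"]
    if sr > rapid_cut:
        return "rapid"
    return "unclassified"


# Theoretical (binomial) FDR -------------------------------------------


def _binom_distances(length: int, p: float, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-count probabilities and distances for k ~ Binomial(length, p).

    In ``jukes_cantor`` mode counts with k/length >= 0.75 are saturated and
    mapped to +inf (they exceed any SR threshold when in the numerator).
    """
    k = np.arange(length + 1)
    probs = stats.binom.pmf(k, length, p)
    if mode == "count":
        d = k / length
    elif mode == "jukes_cantor":
        frac = k / length
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(frac < 0.75, -0.75 * np.log1p(-4.0 * frac / 3.0), np.inf)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return probs, d


def theoretical_fdr(
    p_neutral: float,
    len_feature: int,
    len_null: int,
    sr_threshold: float = 2.0,
    distance_mode: str = "count",
    prior_null: float | None = None,
    alt_exceedance: float | None = None,
) -> tuple[float, float | None]:
    """Null exceedance P(SR > threshold) under the independent-substitution model.

    Both a neutral feature of ``len_feature`` sites and its neutral model of
    ``len_null`` sites acquire substitutions independently with probability
    ``p_neutral`` per site, so both substitution counts are binomial; the SR
    is their (length-normalized) ratio. The exceedance is computed by exact
    summation over the joint count distribution. Zero-count convention: a
    zero null count leaves SR undefined and never exceeds; a zero feature
    count gives SR = 0.

    Converting the exceedance into a full FDR requires a prior mixture:
    when ``prior_null`` (fraction of truly neutral features) and
    ``alt_exceedance`` (exceedance probability for a truly rapid feature)
    are both given, the second return value is
    prior_null * exceedance / (prior_null * exceedance +
    (1 - prior_null) * alt_exceedance); otherwise it is None.
    """
    if not 0 < p_neutral < 0.75:
        raise ValueError(f"p_neutral {p_neutral} outside (0, 0.75)")
    if len_feature < 1 or len_null < 1:
        raise ValueError("lengths must be >= 1")
    pf, df = _binom_distances(len_feature, p_neutral, distance_mode)
    pn, dn = _binom_distances(len_null, p_neutral, distance_mode)
    # exceed iff null distance is positive and finite and d_F / d_LN > threshold
    valid_null = (dn > 0) & np.isfinite(dn)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df[:, None] / dn[None, :]
    exceed = valid_null[None, :] & (ratio > sr_threshold)
    # inf/inf (both saturated) is nan -> not exceeding
    exceed &= ~np.isnan(ratio)
    exceedance = float(np.sum(pf[:, None] * pn[None, :] * exceed))
    implied = None
    if prior_null is not None and alt_exceedance is not None:
        num = prior_null * exceedance
        den = num + (1.0 - prior_null) * alt_exceedance
        implied = num / den if den > 0 else math.nan
    return exceedance, implied
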