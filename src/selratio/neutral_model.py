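"""Ancestral-repeat selection and the local neutral model.

Ancestral repeats (ARs) — transposable-element copies already present in
the human/mouse common ancestor — serve as the local proxy for neutral
evolution. Repeats are admitted by the Yang criteria (shared lineage, not
Alu, sufficiently diverged from the reconstructed ancestral consensus, and
aligned in all analysis species). Each feature's neutral model is the
concatenation of the nearest gap-free AR positions flanking it: 500 per
side by default, never using positions inside the feature itself. A legacy
variant collects all AR positions within 1 kb instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomicInterval


class NoNeutralModelError(ValueError):
    """No ancestral-repeat positions available around the feature."""


@dataclass
class AncestralRepeat:
    interval: GenomicInterval
    family: str
    repeat_class: str
    divergence: float  # percent from the reconstructed ancestral consensus
    lineage: str  # primate_specific | rodent_specific | shared
    ar_id: str = ""
    # filled by attach_alignment: pairwise gap-free sequences + ref coords
    seq_ref: str = ""
    seq_other: str = ""
    ref_coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.ar_id:
            self.ar_id = self.interval.name or (
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def degapped_length(self) -> int:
        return len(self.seq_ref)

    def attach_alignment(self, seq_ref: str, seq_other: str, ref_coords: np.ndarray) -> None:
        if len(seq_ref) != len(seq_other) or len(seq_ref) != len(ref_coords):
            raise ValueError("degapped sequences and coordinates must have equal length")
        if len(ref_coords) > 1 and not (np.diff(ref_coords) > 0).all():
            raise ValueError("reference coordinates must be strictly increasing")
        self.seq_ref = seq_ref
        self.seq_other = seq_other
        self.ref_coords = np.asarray(ref_coords, dtype=np.int64)


@dataclass
class LocalNeutralModel:
    feature_id: str
    upstream_positions: int
    downstream_positions: int
    seq_ref: str
    seq_other: str
    contributing_ars: list[tuple[str, int]]
    complete: bool
    shortfall_side: str | None = None
    positions: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_positions(self) -> int:
        return self.upstream_positions + self.downstream_positions


def _is_alu(rec: AncestralRepeat) -> bool:
    return "ALU" in rec.repeat_class.upper() or rec.family.upper().startswith("ALU")


def _is_l1(rec: AncestralRepeat) -> bool:
    return rec.repeat_class.upper() in ("LINE/L1", "L1") or rec.family.upper().startswith("L1")


def select_ancestral_repeats(
    repeats: list[AncestralRepeat],
    alignment_presence: dict[str, set[str]] | None = None,
    required_species: tuple[str, ...] = (),
) -> list[AncestralRepeat]:
    """Retain repeats that qualify as ancestral under the Yang criteria.

    A repeat is kept iff it is of shared (non-primate-specific,
    non-rodent-specific) lineage, is not an Alu element, is diverged more
    than 25% from its reconstructed ancestral consensus (more than 20% for
    L1 elements), and — when ``alignment_presence`` is supplied — is aligned
    in every species of ``required_species``. Records with a missing
    divergence are skipped with a warning.
    """
    selected = []
    for rec in repeats:
        if rec.divergence is None or (
            isinstance(rec.divergence, float) and np.isnan(rec.divergence)
        ):
            warnings.warn(f"repeat {rec.ar_id}: missing divergence, skipped")
            continue
        if rec.lineage != "shared":
            continue
        if _is_alu(rec):
            continue
        threshold = 20.0 if _is_l1(rec) else 25.0
        if not rec.divergence > threshold:
            continue
        if alignment_presence is not None and required_species:
            present = alignment_presence.get(rec.ar_id, set())
            if not set(required_species) <= present:
                continue
        selected.append(rec)
    return selected


class ArPositionIndex:
    """Per-chromosome sorted index of de-gapped AR positions.

    Each position carries the reference base, the partner-species base and
    the id of the contributing AR, sorted by reference coordinate.
    """

    def __init__(self, ars: list[AncestralRepeat]):
        by_chrom: dict[str, list] = {}
        for ar in ars:
            if ar.ref_coords is None or len(ar.ref_coords) == 0:
                continue
            by_chrom.setdefault(ar.interval.chrom, []).append(ar)
        self._chroms: dict[str, dict] = {}
        for chrom, group in by_chrom.items():
            coords = np.concatenate([ar.ref_coords for ar in group])
            ref = np.concatenate(
                [np.frombuffer(ar.seq_ref.encode(), dtype="S1") for ar in group]
            )
            other = np.concatenate(
                [np.frombuffer(ar.seq_other.encode(), dtype="S1") for ar in group]
            )
            ids = np.concatenate(
                [np.full(len(ar.ref_coords), i) for i, ar in enumerate(group)]
            )
            order = np.argsort(coords, kind="stable")
            self._chroms[chrom] = {
                "coords": coords[order],
                "ref": ref[order],
                "other": other[order],
                "ids": ids[order],
                "ars": group,
            }

    def chrom_data(self, chrom: str) -> dict | None:
        return self._chroms.get(chrom)


def _collect_side(data, mask, nearest_first_order, k):
    """Indices of up to k positions on one side, nearest first."""
    idx = np.nonzero(mask)[0][nearest_first_order]
    return idx[:k]


def build_local_neutral(
    feature: GenomicInterval,
    index: ArPositionIndex,
    flank: int = 500,
    borrow: bool = True,
    exclude_ar_id: str | None = None,
    max_radius: int | None = None,
    measure_from: str = "boundary",
) -> LocalNeutralModel:
    """Concatenate the nearest ``flank`` AR positions on each side of a feature.

    Walks outward from the feature's 5' and 3' boundaries collecting
    de-gapped AR positions in order of increasing distance; positions inside
    the feature are never used. With ``borrow`` (the default), a side that
    cannot supply ``flank`` positions is topped up from the other side's
    next-nearest positions so the denominator keeps 2 x flank positions
    whenever the chromosome can supply them. Output sequences are in genomic
    order (5' block, then 3' block).
    """
    data = index.chrom_data(feature.chrom)
    if data is None:
        raise NoNeutralModelError(f"no AR positions on {feature.chrom}")
    coords = data["coords"]
    eligible = np.ones(len(coords), dtype=bool)
    if exclude_ar_id is not None:
        ids = data["ids"]
        ars = data["ars"]
        excluded = {i for i, ar in enumerate(ars) if ar.ar_id == exclude_ar_id}
        if excluded:
            eligible &= ~np.isin(ids, list(excluded))
    if measure_from == "midpoint":
        anchor5 = anchor3 = (feature.start + feature.end) // 2
        up_mask = eligible & (coords < feature.start)
        down_mask = eligible & (coords >= feature.end)
        up_dist = anchor5 - coords
        down_dist = coords - anchor3
    else:
        up_mask = eligible & (coords < feature.start)
        down_mask = eligible & (coords >= feature.end)
        up_dist = feature.start - coords  # >= 1 for upstream positions
        down_dist = coords - feature.end + 1
    if max_radius is not None:
        up_mask &= up_dist <= max_radius
        down_mask &= down_dist <= max_radius

    up_idx_all = np.nonzero(up_mask)[0][::-1]  # nearest (largest coord) first
    down_idx_all = np.nonzero(down_mask)[0]  # nearest (smallest coord) first
    if len(up_idx_all) == 0 and len(down_idx_all) == 0:
        raise NoNeutralModelError(
            f"no AR positions around feature {feature.name or feature.chrom}"
        )

    n_up = min(flank, len(up_idx_all))
    n_down = min(flank, len(down_idx_all))
    shortfall_side = None
    if borrow:
        if n_up < flank:
            shortfall_side = "5prime"
            extra = min(flank - n_up, len(down_idx_all) - n_down)
            n_down += extra
        elif n_down < flank:
            shortfall_side = "3prime"
            extra = min(flank - n_down, len(up_idx_all) - n_up)
            n_up += extra
    else:
        if n_up < flank:
            shortfall_side = "5prime"
        if n_down < flank:
            shortfall_side = "3prime" if shortfall_side is None else "both"

    up_idx = np.sort(up_idx_all[:n_up])
    down_idx = np.sort(down_idx_all[:n_down])
    chosen = np.concatenate([up_idx, down_idx])
    seq_ref = data["ref"][chosen].tobytes().decode()
    seq_other = data["other"][chosen].tobytes().decode()
    ids_used = data["ids"][chosen]
    ars = data["ars"]
    contributing = []
    for i in np.unique(ids_used):
        contributing.append((ars[int(i)].ar_id, int((ids_used == i).sum())))
    total = n_up + n_down
    return LocalNeutralModel(
        feature_id=feature.name or f"{feature.chrom}:{feature.start}-{feature.end}",
        upstream_positions=int(n_up),
        downstream_positions=int(n_down),
        seq_ref=seq_ref,
        seq_other=seq_other,
        contributing_ars=contributing,
        complete=(total == 2 * flank),
        shortfall_side=shortfall_side,
        positions=coords[chosen],
    )


def legacy_local_neutral_1kb(
    feature: GenomicInterval,
    index: ArPositionIndex,
    window: int = 1000,
    exclude_ar_id: str | None = None,
) -> LocalNeutralModel:
    """All de-gapped AR positions within ``window`` bp of the feature boundaries.

    Variable-length variant of the null model: every eligible position within
    1 kb contributes, however many there are.
    """
    data = index.chrom_data(feature.chrom)
    if data is None:
        raise NoNeutralModelError(f"no AR positions on {feature.chrom}")
    coords = data["coords"]
    eligible = np.ones(len(coords), dtype=bool)
    if exclude_ar_id is not None:
        ars = data["ars"]
        excluded = {i for i, ar in enumerate(ars) if ar.ar_id == exclude_ar_id}
        if excluded:
            eligible &= ~np.isin(data["ids"], list(excluded))
    up = eligible & (coords < feature.start) & (coords >= feature.start - window)
    down = eligible & (coords >= feature.end) & (coords < feature.end + window)
    chosen = np.nonzero(up | down)[0]
    if len(chosen) == 0:
        raise NoNeutralModelError(
            f"no AR positions within {window} bp of {feature.name or feature.chrom}"
        )
    n_up = int(up.sum())
    n_down = int(down.sum())
    ids_used = data["ids"][chosen]
    ars = data["ars"]
    contributing = [
        (ars[int(i)].ar_id, int((ids_used == i).sum())) for i in np.unique(ids_used)
    ]
    return LocalNeutralModel(
        feature_id=feature.name or f"{feature.chrom}:{feature.start}-{feature.end}",
        upstream_positions=n_up,
        downstream_positions=n_down,
        seq_ref=data["ref"][chosen].tobytes().decode(),
        seq_other=data["other"][chosen].tobytes().decode(),
        contributing_ars=contributing,
        complete=True,
        shortfall_side=None,
        positions=coords[chosen],
    )
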