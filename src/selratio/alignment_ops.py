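"""Sub-alignment extraction, de-gapping, covariates and feature filters.

A feature's 3-way alignment is stitched from the MAF blocks overlapping it
on the reference, then every column with a gap in any species is removed.
Covariates computed on the de-gapped alignment (G+C of the reference
sequence, pairwise sequence identity to the distance partner, de-gapped
column count) feed the binned false-discovery-rate estimate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_io import AlignmentBlock, GenomicInterval


class UnanchoredError(ValueError):
    """Feature not covered by the alignment, or a species absent everywhere."""


class StructureFormatError(ValueError):
    """Dot-bracket string is unbalanced or mismatched in length."""


@dataclass
class ThreeWayAlignment:
    """Gapped aligned sequences over one feature locus, reference species first.

    ``ref_coords[j]`` is the reference genome coordinate of column ``j``, or
    -1 for columns where the reference row is gapped.
    """

    feature_id: str
    species: tuple[str, ...]
    aligned: tuple[str, ...]
    ref_interval: GenomicInterval
    ref_coords: np.ndarray = field(repr=False, default=None)

    @property
    def n_columns(self) -> int:
        return len(self.aligned[0])

    def __post_init__(self):
        widths = {len(s) for s in self.aligned}
        if len(widths) > 1:
            raise ValueError(f"unequal aligned lengths {sorted(widths)}")
        if self.ref_coords is None:
            # columns assumed gap-free in reference, contiguous from start
            ref = self.aligned[0]
            coords = np.full(len(ref), -1, dtype=np.int64)
            pos = self.ref_interval.start
            for j, c in enumerate(ref):
                if c != "-":
                    coords[j] = pos
                    pos += 1
            self.ref_coords = coords


@dataclass
class DegappedAlignment:
    """Gap-free columns of a multi-way alignment plus its covariates."""

    feature_id: str
    species: tuple[str, ...]
    columns: tuple[str, ...]
    n_columns: int
    fraction_removed: float
    gc_ref: float
    si_pairwise: float
    ref_coords: np.ndarray = field(repr=False, default=None)

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


def _slice_block(block: AlignmentBlock, species: tuple[str, ...],
                 start: int, end: int) -> tuple[list[str], np.ndarray] | None:
    """Clip one block to [start, end) on the reference (first species).

    Returns per-species column strings and reference coordinates, or None if
    the block does not overlap the window. Species missing from the block
    contribute gap runs. Interleaved insertion columns (reference gapped)
    between retained reference positions are kept.
    """
    ref_row = block.row_for(species[0])
    if ref_row is None:
        return None
    text = ref_row.text
    ncol = len(text)
    coords = np.full(ncol, -1, dtype=np.int64)
    pos = ref_row.start
    for j, c in enumerate(text):
        if c != "-":
            coords[j] = pos
            pos += 1
    inside = (coords >= start) & (coords < end)
    if not inside.any():
        return None
    j0 = int(np.argmax(inside))
    j1 = ncol - int(np.argmax(inside[::-1]))  # one past last retained column
    cols = []
    for sp in species:
        row = block.row_for(sp)
        cols.append(row.text[j0:j1] if row is not None else "-" * (j1 - j0))
    return cols, coords[j0:j1]


def extract_threeway(
    blocks: list[AlignmentBlock],
    feature: GenomicInterval,
    species: tuple[str, str, str],
) -> ThreeWayAlignment:
    """Stitch the 3-way sub-alignment covering ``feature`` out of MAF blocks.

    Blocks are processed in order of reference start; each is clipped to the
    feature window and the clips concatenated. Raises
    :class:`UnanchoredError` when no block covers the feature or one of the
    species is gap-only over the whole stitched alignment.
    """
    return _extract_subalignment(blocks, feature, species)


def extract_pairwise(
    blocks: list[AlignmentBlock],
    interval: GenomicInterval,
    species: tuple[str, str],
) -> ThreeWayAlignment:
    """Pairwise variant of :func:`extract_threeway` (used for ancestral repeats)."""
    return _extract_subalignment(blocks, interval, species)


def _extract_subalignment(blocks, feature, species):
    pieces = []
    relevant = []
    for block in blocks:
        ref_row = block.row_for(species[0])
        if ref_row is None or ref_row.chrom != feature.chrom:
            continue
        if ref_row.start >= feature.end or ref_row.start + ref_row.size <= feature.start:
            continue
        relevant.append(block)
    relevant.sort(key=lambda b: b.row_for(species[0]).start)
    for block in relevant:
        sliced = _slice_block(block, species, feature.start, feature.end)
        if sliced is not None:
            pieces.append(sliced)
    if not pieces:
        raise UnanchoredError(
            f"feature {feature.name or feature.chrom} not covered by any alignment block"
        )
    aligned = tuple(
        "".join(piece[0][k] for piece in pieces) for k in range(len(species))
    )
    coords = np.concatenate([piece[1] for piece in pieces])
    for sp, seq in zip(species, aligned):
        if all(c == "-" for c in seq):
            raise UnanchoredError(
                f"species {sp} absent over feature {feature.name or feature.chrom}"
            )
    return ThreeWayAlignment(
        feature_id=feature.name or f"{feature.chrom}:{feature.start}-{feature.end}",
        species=tuple(species),
        aligned=aligned,
        ref_interval=feature,
        ref_coords=coords,
    )


def degap(aln: ThreeWayAlignment, pair_index: int = -1) -> DegappedAlignment:
    """Remove every column containing '-' in any species.

    'N' is not a gap: N-containing columns are retained here and excluded
    from substitution counting instead. ``si_pairwise`` is computed between
    the reference and the species at ``pair_index`` (default: last).
    """
    mats = np.array([np.frombuffer(s.encode(), dtype="S1") for s in aln.aligned])
    keep = ~(mats == b"-").any(axis=0)
    kept = mats[:, keep]
    n_total = aln.n_columns
    n_kept = int(keep.sum())
    columns = tuple(k.tobytes().decode() for k in kept)
    ref = kept[0]
    acgt = np.isin(ref, [b"A", b"C", b"G", b"T"])
    gc = np.isin(ref, [b"G", b"C"])
    gc_ref = float(gc.sum() / acgt.sum()) if acgt.sum() else float("nan")
    other = kept[pair_index]
    si = float((ref == other).sum() / n_kept) if n_kept else float("nan")
    return DegappedAlignment(
        feature_id=aln.feature_id,
        species=aln.species,
        columns=columns,
        n_columns=n_kept,
        fraction_removed=(n_total - n_kept) / n_total if n_total else 0.0,
        gc_ref=gc_ref,
        si_pairwise=si,
        ref_coords=aln.ref_coords[keep],
    )


@dataclass
class FilterConfig:
    min_degapped_columns: int = 80
    repeat_overlap: bool = True
    max_bp_gap_fraction: float | None = 0.20
    attribute_filters: dict = field(default_factory=dict)


def feature_filters(
    aln: DegappedAlignment,
    feature: GenomicInterval,
    repeats: list[GenomicInterval],
    cfg: FilterConfig | None = None,
) -> tuple[bool, set[str]]:
    """Apply the retention filters; returns (passed, reason codes).

    Reasons accumulate: ``short`` when the de-gapped column count is below
    the threshold (default 80), ``repeat_overlap`` when the feature interval
    intersects any repeat by >= 1 bp, plus ``attr:<name>`` for configured
    attribute thresholds (e.g. precomputed structure-prediction FDR).
    """
    cfg = cfg or FilterConfig()
    reasons: set[str] = set()
    if aln.n_columns < cfg.min_degapped_columns:
        reasons.add("short")
    if cfg.repeat_overlap and any(feature.overlaps(rep) for rep in repeats):
        reasons.add("repeat_overlap")
    for attr, (op, threshold) in cfg.attribute_filters.items():
        if attr in feature.attributes:
            val = feature.attributes[attr]
            ok = val <= threshold if op == "le" else val >= threshold
            if not ok:
                reasons.add(f"attr:{attr}")
    return (not reasons, reasons)


def parse_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Return 0-based (i, j) basepairs from a dot-bracket string."""
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureFormatError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c not in ".,:_-<>{}[]":
            raise StructureFormatError(f"unexpected character {c!r} at position {i}")
    if stack:
        raise StructureFormatError(f"unclosed '(' at position {stack[-1]}")
    return sorted(pairs)


def basepair_gap_fraction(structure: str, aln: ThreeWayAlignment) -> float:
    """Fraction of consensus basepairs with either paired column gapped anywhere.

    Callers retain features where this is below 0.20.
    """
    if len(structure) != aln.n_columns:
        raise StructureFormatError(
            f"structure length {len(structure)} != alignment width {aln.n_columns}"
        )
    pairs = parse_dotbracket(structure)
    if not pairs:
        return 0.0
    gapped_col = [any(seq[j] == "-" for seq in aln.aligned) for j in range(aln.n_columns)]
    hit = sum(1 for i, j in pairs if gapped_col[i] or gapped_col[j])
    return hit / len(pairs)
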