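"""Feature extraction: per-nucleus averaged chemical shifts and the AAC baseline.

A segment of length *l* is summarised, for each requested nucleus, by the
arithmetic mean of the shift values assigned within the segment:

    t_i = (1/l_i) * sum of CS_i over assigned residues,

giving one feature per nucleus (canonical order C, CA, CB, H, HA, N).  Real
shift data has assignment gaps, so the mean runs over the residues that
actually carry the nucleus (l_i <= l); a segment is only unusable for a run
if some requested nucleus has zero assignments in it.

The amino-acid-composition (AAC) baseline maps the segment sequence to the
20 relative frequencies of the standard amino acids in alphabetical
one-letter order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from shiftmotif.defs import AMINO_ACIDS, NUCLEI, normalize_nucleus
from shiftmotif.io_formats import Segment, ShiftTable

logger = logging.getLogger(__name__)


class MissingFeatureError(ValueError):
    """A requested nucleus has no assigned shifts within the segment."""

    def __init__(self, segment: Segment, nucleus: str) -> None:
        self.segment = segment
        self.nucleus = nucleus
        super().__init__(
            f"segment {segment.describe()}: no {nucleus} shifts assigned"
        )


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, finite feature vector attached to its source segment.

    ``support`` records, for shift features, how many residues contributed
    to each mean (None for AAC vectors).
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    segment_ref: Segment
    label: str | None = None
    support: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 1 or values.size != len(self.feature_names) or values.size < 1:
            raise ValueError(
                f"feature vector shape {values.shape} does not match"
                f" {len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite features for {self.segment_ref.describe()}")

    def __len__(self) -> int:
        return self.values.size


def canonical_nuclei(nuclei: Iterable[str]) -> tuple[str, ...]:
    """Normalize a nucleus subset and order it canonically (C, CA, CB, H, HA, N)."""
    normalized = {normalize_nucleus(n) for n in nuclei}
    if not normalized:
        raise ValueError("empty nucleus subset")
    return tuple(n for n in NUCLEI if n in normalized)


def average_shifts(
    segment: Segment,
    shifts: ShiftTable,
    nuclei: Iterable[str] = NUCLEI,
) -> FeatureVector:
    """Average each requested nucleus's shifts over the segment's residues.

    The mean runs over the residues of the segment that carry an assignment
    for that nucleus; the per-nucleus residue count is reported in
    ``support``.  Raises :class:`MissingFeatureError` if a requested nucleus
    has zero assignments in the segment.
    """
    nuclei = canonical_nuclei(nuclei)
    values = np.empty(len(nuclei))
    support = []
    for k, nuc in enumerate(nuclei):
        assigned = [
            rec.shift_ppm
            for res in segment.residues
            if (rec := shifts.get(segment.protein_id, segment.chain_id, res, nuc))
            is not None
        ]
        if not assigned:
            raise MissingFeatureError(segment, nuc)
        values[k] = float(np.mean(assigned))
        support.append(len(assigned))
    return FeatureVector(
        values=values,
        feature_names=nuclei,
        segment_ref=segment,
        label=segment.label,
        support=tuple(support),
    )


def aac_composition(segment: Segment) -> FeatureVector:
    """Relative frequencies of the 20 standard amino acids in the segment sequence.

    Non-standard letters are excluded from both numerator and denominator
    (logged); a missing sequence, or one containing no standard residues,
    is an error.
    """
    if segment.sequence is None:
        raise ValueError(f"segment {segment.describe()} has no sequence for AAC")
    seq = segment.sequence.upper()
    standard = [c for c in seq if c in AMINO_ACIDS]
    dropped = len(seq) - len(standard)
    if dropped:
        logger.info(
            "segment %s: %d non-standard letters excluded from AAC",
            segment.describe(),
            dropped,
        )
    if not standard:
        raise ValueError(
            f"segment {segment.describe()}: sequence has no standard residues"
        )
    counts = np.array([standard.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return FeatureVector(
        values=counts / counts.sum(),
        feature_names=AMINO_ACIDS,
        segment_ref=segment,
        label=segment.label,
    )


@dataclass(frozen=True)
class Design:
    """A batch of feature vectors plus the segments dropped while building it."""

    vectors: tuple[FeatureVector, ...]
    excluded: tuple[tuple[Segment, str], ...]  # (segment, reason)


def build_design(
    segments: Sequence[Segment],
    shifts: ShiftTable | None = None,
    nuclei: Iterable[str] = NUCLEI,
    mode: str = "cs",
) -> Design:
    """Convert segments to feature vectors, dropping and reporting unusable ones.

    ``mode="cs"`` averages shifts over the given nuclei subset (requires
    ``shifts``); ``mode="aac"`` builds composition vectors (requires segment
    sequences).  Output order follows input order of surviving segments; an
    empty result is an error.
    """
    vectors: list[FeatureVector] = []
    excluded: list[tuple[Segment, str]] = []
    if mode == "cs":
        if shifts is None:
            raise ValueError("mode='cs' requires a shift table")
        nuclei = canonical_nuclei(nuclei)
        for seg in segments:
            try:
                vectors.append(average_shifts(seg, shifts, nuclei))
            except MissingFeatureError as exc:
                excluded.append((seg, f"no {exc.nucleus} assignments"))
    elif mode == "aac":
        for seg in segments:
            try:
                vectors.append(aac_composition(seg))
            except ValueError as exc:
                excluded.append((seg, str(exc)))
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    if not vectors:
        raise ValueError("every segment was dropped while building the design")
    if excluded:
        logger.info("build_design: %d of %d segments excluded", len(excluded), len(segments))
    return Design(vectors=tuple(vectors), excluded=tuple(excluded))
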