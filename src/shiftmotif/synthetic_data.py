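"""Synthetic motif datasets with known class-conditional structure.

Each synthetic segment draws one latent six-nucleus shift vector from its
class's multivariate Gaussian; every residue of the segment then emits
latent value + independent N(0, residue_noise_sd^2) noise per nucleus, and
each emitted record is dropped with probability ``missing_rate``.  Class
signal therefore lives at segment level and noise at residue level, which
mirrors the feature definition (per-segment averaging of residue shifts)
and lets tests control separability exactly.

Default class means sit near random-coil backbone values with helix/strand
offsets of the sign and rough size seen in secondary-structure shift
statistics (helix raises CA and C and lowers HA; strand does the opposite
and raises CB); mixed classes (HE, EH) average the two elements with the
first element weighted more, so HE and EH remain distinct.  These defaults
make fixtures look plausible; they are configuration, not contract.

Default class counts are 90/89/97/122 (HH/HE/EH/EE), the composition of the
benchmark motif set this tool is aimed at.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from shiftmotif.defs import AMINO_ACIDS, CLASSES, NUCLEI
from shiftmotif.io_formats import (
    Segment,
    ShiftRecord,
    ShiftTable,
    write_fasta,
    write_segments,
    write_shift_table,
)

#: Random-coil-like backbone baseline (ppm) in canonical nucleus order.
_COIL = np.array([176.0, 55.0, 38.5, 8.25, 4.45, 119.5])
#: Helix and strand offsets from the baseline (ppm).
_HELIX = np.array([1.8, 2.6, -0.6, -0.25, -0.32, -1.6])
_STRAND = np.array([-1.2, -1.6, 2.2, 0.35, 0.42, 2.4])
#: Per-nucleus between-segment SDs (ppm): carbons ~1 ppm, protons fractions
#: of a ppm, nitrogen widest.
_SCALE = np.array([1.1, 1.2, 1.4, 0.30, 0.25, 2.4])

#: First secondary-structure element weighted more than the second so the
#: two mixed classes (HE vs EH) have distinct means.
_ELEMENT_WEIGHTS = (0.62, 0.38)


def _default_means() -> dict[str, np.ndarray]:
    w1, w2 = _ELEMENT_WEIGHTS
    elem = {"H": _HELIX, "E": _STRAND}
    return {
        cls: _COIL + w1 * elem[cls[0]] + w2 * elem[cls[1]] for cls in CLASSES
    }


def _default_covariances() -> dict[str, np.ndarray]:
    return {cls: np.diag(_SCALE**2) for cls in CLASSES}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; defaults emulate the benchmark composition.

    ``class_means``/``class_covariances`` are per-class 6-vectors / SPD 6x6
    matrices in canonical nucleus order (ppm); ``counts`` are segments per
    class; segment lengths are uniform over ``length_range`` (residues);
    ``residue_noise_sd`` is the per-residue, per-nucleus observation noise
    (ppm); ``missing_rate`` is the probability an individual assignment is
    absent.
    """

    class_means: Mapping[str, np.ndarray] = field(default_factory=_default_means)
    class_covariances: Mapping[str, np.ndarray] = field(
        default_factory=_default_covariances
    )
    counts: Mapping[str, int] = field(
        default_factory=lambda: {"HH": 90, "HE": 89, "EH": 97, "EE": 122}
    )
    length_range: tuple[int, int] = (6, 16)
    residue_noise_sd: float = 0.5
    missing_rate: float = 0.1
    seed: int = 20140618

    def __post_init__(self) -> None:
        means = {c: np.asarray(m, dtype=float) for c, m in self.class_means.items()}
        covs = {
            c: np.asarray(S, dtype=float) for c, S in self.class_covariances.items()
        }
        object.__setattr__(self, "class_means", means)
        object.__setattr__(self, "class_covariances", covs)
        for c, S in covs.items():
            if not np.allclose(S, S.T):
                raise ValueError(f"class {c}: covariance not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"class {c}: covariance not positive-definite")
            if means[c].size != S.shape[0]:
                raise ValueError(f"class {c}: mean/covariance dimension mismatch")
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("counts must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.residue_noise_sd < 0:
            raise ValueError("residue_noise_sd must be >= 0")

    def to_json(self) -> str:
        payload = {
            "class_means": {c: m.tolist() for c, m in self.class_means.items()},
            "class_covariances": {
                c: S.tolist() for c, S in self.class_covariances.items()
            },
            "counts": dict(self.counts),
            "length_range": list(self.length_range),
            "residue_noise_sd": self.residue_noise_sd,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        p = json.loads(text)
        return cls(
            class_means={c: np.asarray(m) for c, m in p["class_means"].items()},
            class_covariances={
                c: np.asarray(S) for c, S in p["class_covariances"].items()
            },
            counts=p["counts"],
            length_range=tuple(p["length_range"]),
            residue_noise_sd=p["residue_noise_sd"],
            missing_rate=p["missing_rate"],
            seed=p["seed"],
        )


@dataclass(frozen=True)
class SyntheticDataset:
    segments: tuple[Segment, ...]
    shifts: ShiftTable
    sequences: dict[str, str]
    latent: dict[str, np.ndarray]  # protein_id -> latent 6-vector


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a full dataset (segments, residue-level shift records, sequences).

    Each segment lives on its own synthetic protein (chain A, residues
    numbered from 1).  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[Segment] = []
    table = ShiftTable()
    sequences: dict[str, str] = {}
    latent: dict[str, np.ndarray] = {}
    counter = 0
    for cls in CLASSES:
        n = int(spec.counts.get(cls, 0))
        if n == 0:
            continue
        mean = spec.class_means[cls]
        cov = spec.class_covariances[cls]
        chol = np.linalg.cholesky(cov)
        for _ in range(n):
            counter += 1
            pid = f"syn{counter:04d}"
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            center = mean + chol @ rng.standard_normal(mean.size)
            latent[pid] = center
            sequences[pid] = seq
            segments.append(
                Segment(pid, "A", 1, length, label=cls, sequence=seq)
            )
            noise = rng.normal(0.0, spec.residue_noise_sd, size=(length, len(NUCLEI)))
            keep = rng.random((length, len(NUCLEI))) >= spec.missing_rate
            for r in range(length):
                for k, nuc in enumerate(NUCLEI):
                    if keep[r, k]:
                        table.add(
                            ShiftRecord(
                                pid, "A", r + 1, seq[r], nuc, center[k] + noise[r, k]
                            )
                        )
    return SyntheticDataset(
        segments=tuple(segments), shifts=table, sequences=sequences, latent=latent
    )


def write_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a dataset and write it as files the readers consume end-to-end.

    Emits ``shifts.tsv``, ``segments.tsv``, ``sequences.fasta`` and the spec
    itself as ``spec.json``; returns the paths.  Byte-identical across runs
    with the same spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(spec)
    paths = {
        "shifts": out_dir / "shifts.tsv",
        "segments": out_dir / "segments.tsv",
        "fasta": out_dir / "sequences.fasta",
        "spec": out_dir / "spec.json",
    }
    write_shift_table(ds.shifts, paths["shifts"])
    write_segments(ds.segments, paths["segments"])
    write_fasta(ds.sequences, paths["fasta"])
    paths["spec"].write_text(spec.to_json(), encoding="utf-8")
    return paths
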