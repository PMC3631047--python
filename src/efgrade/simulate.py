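"""Synthetic reader studies and mask phantoms.

Two generators make every stage of the pipeline testable without image
data: :func:`simulate_reader_study` draws multi-reader multi-occasion
ordinal score tables from a latent additive model, and
:func:`simulate_slice_masks` builds binary canal/fibrosis phantoms with
known per-quadrant affected fractions.

The reader-study model is

    score(i, r, o) = round+clamp( mu_i + b_r + eps_iro )

with patient effects ``mu_i ~ N(mean, between_patient_sd^2)`` drawn once
per patient, fixed per-reader biases ``b_r``, and occasion noise
``eps ~ N(0, occasion_noise_sd^2)``.  With no reader bias the theoretical
single-rating reliability is the variance ratio
``sigma_b^2 / (sigma_b^2 + sigma_e^2)`` (discretization aside), which the
ICC estimators should recover as the number of patients grows.

Defaults mirror the bundled validation study's design (32 patients, two
readers, two occasions) with moments chosen to loosely match its spread;
they are conventions, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .masks import GeometryError, SliceGeometry
from .reliability import ReaderStudyTable

__all__ = ["SimulationParams", "simulate_reader_study", "simulate_slice_masks"]


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for a synthetic reader study.

    ``score_range`` bounds the ordinal scale; the default (0, 80) is a
    5-slice segment total (5 x 16).  ``mean_score`` centres the patient
    effects; the default spread roughly matches the bundled study
    (between-patient SD ~5, occasion SD ~1).
    """

    n_patients: int = 32
    n_readers: int = 2
    n_occasions: int = 2
    between_patient_sd: float = 5.0
    reader_bias: tuple[float, ...] = (0.0, 0.0)
    occasion_noise_sd: float = 1.0
    mean_score: float = 9.0
    score_range: tuple[int, int] = (0, 80)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_readers, self.n_occasions) < 1:
            raise SimulationError("counts must all be >= 1")
        if self.between_patient_sd < 0 or self.occasion_noise_sd < 0:
            raise SimulationError("standard deviations must be >= 0")
        if len(self.reader_bias) != self.n_readers:
            raise SimulationError(
                f"need one bias per reader: {self.n_readers} readers, "
                f"{len(self.reader_bias)} biases"
            )
        lo, hi = self.score_range
        if not lo < hi:
            raise SimulationError("score_range min must be < max")


def simulate_reader_study(params: SimulationParams) -> ReaderStudyTable:
    """Draw a reader-study score table from the latent additive model.

    Deterministic for a fixed ``params.seed``.  Scores are rounded to the
    nearest integer and clamped to ``score_range``, emulating ordinal
    grading of a continuous fibrosis burden.
    """
    rng = np.random.default_rng(params.seed)
    mu = rng.normal(params.mean_score, params.between_patient_sd, params.n_patients)
    eps = rng.normal(
        0.0,
        params.occasion_noise_sd,
        (params.n_patients, params.n_readers, params.n_occasions),
    )
    latent = mu[:, None, None] + np.asarray(params.reader_bias)[None, :, None] + eps
    lo, hi = params.score_range
    scores = np.clip(np.rint(latent), lo, hi).astype(int)

    patients = [str(i + 1) for i in range(params.n_patients)]
    readers = [f"R{r + 1}" for r in range(params.n_readers)]
    occasions = [str(o + 1) for o in range(params.n_occasions)]
    records = [
        {
            "patient_id": patients[i],
            "reader_id": readers[r],
            "occasion": occasions[o],
            "score": scores[i, r, o],
        }
        for i in range(params.n_patients)
        for r in range(params.n_readers)
        for o in range(params.n_occasions)
    ]
    return ReaderStudyTable(pd.DataFrame.from_records(records))


def simulate_slice_masks(
    fractions: Sequence[float],
    raster_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    canal_margin: float = 0.1,
) -> tuple[SliceGeometry, dict[str, float]]:
    """Build a canal/fibrosis phantom with known per-quadrant fractions.

    The canal is a centred rectangle covering the raster minus
    ``canal_margin`` on each side; within each quadrant a random subset of
    evaluation pixels is marked fibrotic so the realized fraction matches
    the request to within one pixel of quadrant area.

    Returns the geometry plus the realized fractions (ground truth) keyed
    by quadrant label.
    """
    from .masks import partition_quadrants  # local import avoids cycle at module load

    fractions = [float(f) for f in fractions]
    if len(fractions) != 4 or any(not 0.0 <= f <= 1.0 for f in fractions):
        raise SimulationError("need four fractions in [0, 1], one per quadrant A-D")
    nrows, ncols = raster_size
    r0, r1 = int(round(nrows * canal_margin)), int(round(nrows * (1 - canal_margin)))
    c0, c1 = int(round(ncols * canal_margin)), int(round(ncols * (1 - canal_margin)))
    if r1 - r0 < 4 or c1 - c0 < 4:
        raise SimulationError(f"raster {raster_size} too small for a quadrant phantom")
    canal = np.zeros((nrows, ncols), dtype=bool)
    canal[r0:r1, c0:c1] = True
    center = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)

    geometry = SliceGeometry(
        canal_mask=canal, fibrosis_mask=np.zeros_like(canal), center=center
    )
    labels = partition_quadrants(geometry)

    rng = np.random.default_rng(seed)
    fib = np.zeros_like(canal)
    realized: dict[str, float] = {}
    for q, frac in zip(("A", "B", "C", "D"), fractions):
        idx = np.flatnonzero(labels.ravel() == q)
        if idx.size < 4:
            raise SimulationError("quadrant too small to realize a fraction")
        n_set = int(round(frac * idx.size))
        chosen = rng.choice(idx, size=n_set, replace=False)
        fib.ravel()[chosen] = True
        realized[q] = n_set / idx.size
    try:
        geom = SliceGeometry(canal_mask=canal, fibrosis_mask=fib, center=center)
    except GeometryError:  # pragma: no cover - construction guarantees subset
        raise
    return geom, realized
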