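"""Bundled validation data: the two-radiologist reading study.

The package ships the per-patient total fibrosis scores from the reading
study that validated the grading model: 32 postoperative lumbar-spine
patients, each scored independently by two radiologists on two occasions
three weeks apart (128 scores).  Scores are per-segment totals (summed
quadrant grades over the graded slices of the operative level).

The transcription is guarded by a self-test: the paired first-vs-second
reading differences must reproduce the study's published intraobserver
summary (radiologist 1: mean 0.06, SD ~1.47-1.48; radiologist 2: mean
-0.25, SD 1.16) or :func:`reading_study` raises.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .reliability import ReaderStudyTable, ReliabilityError

__all__ = ["reading_study"]

_FIXTURE = "reading_study_scores.csv"

# Published intraobserver paired summaries (mean, SD) with transcription
# tolerance; the printed SD 1.47 for reader R1 is a truncation of 1.4797.
_EXPECTED = {"R1": (0.06, 1.47), "R2": (-0.25, 1.16)}


def _load_frame() -> pd.DataFrame:
    with resources.files("efgrade.data").joinpath(_FIXTURE).open() as fh:
        return pd.read_csv(fh, dtype={"patient_id": str, "reader_id": str, "occasion": str})


def reading_study(self_test: bool = True) -> ReaderStudyTable:
    """The bundled 32-patient, 2-reader, 2-occasion score table.

    With ``self_test=True`` (default) the paired-difference summaries are
    checked against the published values so that transcription drift fails
    loudly.
    """
    table = ReaderStudyTable(_load_frame())
    if self_test:
        if len(table.data) != 128 or table.n_patients != 32:
            raise ReliabilityError("bundled reading study has wrong dimensions")
        occ = table.occasions
        for reader, (mean, sd) in _EXPECTED.items():
            d = table.scores(reader, occ[0]) - table.scores(reader, occ[1])
            if abs(d.mean() - mean) > 0.005 or abs(d.std(ddof=1) - sd) > 0.011:
                raise ReliabilityError(
                    f"bundled scores for reader {reader} no longer reproduce the "
                    f"published paired summary (got mean {d.mean():.3f}, SD {d.std(ddof=1):.3f})"
                )
    return table
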