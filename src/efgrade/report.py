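"""Assemble the full observer-reliability report for a reader study.

For a two-reader, two-occasion study the report contains:

* intraobserver paired t-tests (first vs second reading, per reader),
* interobserver unpaired t-tests (reader 1 vs reader 2, per occasion),
* the interobserver ICC with 95 % CI under the configured form,
* Bland-Altman repeatability/agreement summaries.
"""

from __future__ import annotations

import dataclasses
from typing import Any

from .io import StudyConfig
from .reliability import (
    ReaderStudyTable,
    ReliabilityError,
    bland_altman,
    icc,
    paired_ttest,
    unpaired_ttest,
)

__all__ = ["reliability_report", "format_report_text"]


def _as_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def reliability_report(
    table: ReaderStudyTable, config: StudyConfig | None = None
) -> dict[str, Any]:
    """Compute all agreement statistics for a study table as a JSON-able dict."""
    config = config or StudyConfig()
    if config.occasion_order is not None:
        table = ReaderStudyTable(table.data, occasion_order=config.occasion_order)
    occasions = table.occasions
    readers = table.readers

    out: dict[str, Any] = {
        "n_patients": table.n_patients,
        "readers": readers,
        "occasions": occasions,
        "config": config.to_dict(),
    }

    intra = {}
    agreement = {}
    if len(occasions) >= 2:
        o1, o2 = occasions[0], occasions[1]
        for r in readers:
            a, b = table.scores(r, o1), table.scores(r, o2)
            intra[r] = _as_dict(paired_ttest(a, b))
            ba = bland_altman(a, b)
            agreement[r] = {
                k: v
                for k, v in _as_dict(ba).items()
                if k not in ("means", "diffs")
            }
    out["intraobserver_paired_t"] = intra
    out["repeatability"] = agreement

    inter_t = {}
    inter_ba = {}
    if len(readers) == 2:
        r1, r2 = readers
        for o in occasions:
            a, b = table.scores(r1, o), table.scores(r2, o)
            inter_t[o] = _as_dict(unpaired_ttest(a, b, flavor=config.ttest_flavor))
            inter_ba[o] = {
                k: v
                for k, v in _as_dict(bland_altman(a, b)).items()
                if k not in ("means", "diffs")
            }
    out["interobserver_unpaired_t"] = inter_t
    out["interobserver_agreement"] = inter_ba

    if len(readers) >= 2 and table.n_patients >= 3:
        try:
            mat = table.rating_matrix(occasion=config.icc_occasion)
            out["interobserver_icc"] = _as_dict(icc(mat, form=config.icc_form))
            out["interobserver_icc"]["occasion_subset"] = config.icc_occasion
        except ReliabilityError as exc:
            out["interobserver_icc"] = {"error": str(exc)}
    return out


def format_report_text(report: dict[str, Any], precision: int = 2) -> str:
    """Human-readable table mirroring the published layout (Mean, SD, SEM, 95 % CI, P)."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}f}"

    lines = [
        f"Reader study: {report['n_patients']} patients, "
        f"readers {', '.join(report['readers'])}, "
        f"occasions {', '.join(report['occasions'])}",
        "",
        f"{'Variability':<28}{'Mean':>8}{'SD':>8}{'SEM':>8}{'95 % CI':>18}{'P':>8}",
    ]
    if report["intraobserver_paired_t"]:
        lines.append("Intraobserver (paired t, first vs second reading)")
        for reader, res in report["intraobserver_paired_t"].items():
            ci = f"{fmt(res['ci95'][0])} to {fmt(res['ci95'][1])}"
            lines.append(
                f"  {'Reader ' + reader:<26}{fmt(res['mean_diff']):>8}"
                f"{fmt(res['sd_diff']):>8}{fmt(res['sem']):>8}{ci:>18}{fmt(res['p_value']):>8}"
            )
    if report["interobserver_unpaired_t"]:
        lines.append("Interobserver (unpaired t, reader vs reader)")
        for occ, res in report["interobserver_unpaired_t"].items():
            ci = f"{fmt(res['ci95'][0])} to {fmt(res['ci95'][1])}"
            lines.append(
                f"  {'Occasion ' + occ:<26}{fmt(res['mean_diff']):>8}"
                f"{fmt(res['sd_diff']):>8}{fmt(res['sem']):>8}{ci:>18}{fmt(res['p_value']):>8}"
            )
    icc_res = report.get("interobserver_icc")
    if icc_res and "icc" in icc_res:
        lines += [
            "",
            f"Interobserver ICC: {fmt(icc_res['icc'])} "
            f"(95 % CI {fmt(icc_res['ci95'][0])}-{fmt(icc_res['ci95'][1])}); "
            f"{icc_res['model_label']}; occasions: {icc_res['occasion_subset']}",
        ]
    return "\n".join(lines) + "\n"
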