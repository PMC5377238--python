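"""Report rendering: human-readable summaries plus machine-readable JSON/TSV.

Cascade accounting follows the molecule-numbers-with-percentages style: each
stage shows its survivor count and the percentage relative to the stage
before it (the published screen reads 26,368 of 197,211 past the first
filter, i.e. 13.4 %, and 2,273 of those past the second, i.e. 8.6 %).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assay_kinetics import InhibitionResult, KineticFit
from .pose_triage import CascadeReport

__all__ = [
    "render_cascade",
    "cascade_to_json",
    "cascade_to_tsv",
    "render_kinetic_fit",
    "screening_table",
]


def render_cascade(report: CascadeReport) -> str:
    """One line per stage: ``name: count (pct% of previous)``."""
    lines = []
    for i, (name, count) in enumerate(zip(report.stage_names, report.stage_counts)):
        if i == 0:
            lines.append(f"{name}: {count:,}")
        else:
            lines.append(f"{name}: {count:,} ({report.stage_percentages[i]:.1f}%)")
    return "\n".join(lines)


def cascade_to_json(report: CascadeReport, path: str | Path | None = None) -> str:
    """Schema-stable JSON rendering; also includes percentages of the
    original input for convenience."""
    doc = report.to_dict()
    total = report.stage_counts[0] if report.stage_counts else 0
    doc["stage_percentages_of_input"] = [
        100.0 * c / total if total else 0.0 for c in report.stage_counts
    ]
    text = json.dumps(doc, indent=1, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def cascade_to_tsv(report: CascadeReport, path: str | Path) -> None:
    """Per-molecule rule verdicts as a TSV table."""
    rows = []
    for mol, d in report.per_molecule_decisions.items():
        rows.append({"molecule_id": mol, **d})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def render_kinetic_fit(fit: KineticFit) -> str:
    lines = [
        f"Km      = {fit.Km:.3g} +/- {fit.se_Km:.2g} uM",
        f"Vmax    = {fit.Vmax:.3g} +/- {fit.se_Vmax:.2g} uM/min",
        f"kcat    = {fit.kcat:.3g} 1/s  (assuming {fit.enzyme_uM:g} uM fully active enzyme)",
        f"kcat/Km = {fit.kcat_over_Km:.3g} 1/(M s)",
        f"R^2     = {fit.r_squared:.4f}",
    ]
    if not fit.km_identifiable:
        lines.append("warning: Km not identifiable from these data (no curvature)")
    return "\n".join(lines)


def screening_table(results: Sequence[InhibitionResult], path: str | Path | None = None) -> pd.DataFrame:
    """Screening results as a DataFrame sorted by inhibition descending;
    optionally written as TSV."""
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "concentration_uM": r.concentration_uM,
                "inhibition_pct": r.inhibition_pct,
                "background_flag": r.background_flag.value,
            }
            for r in results
        ]
    )
    if not df.empty:
        df = df.sort_values("inhibition_pct", ascending=False).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return df
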