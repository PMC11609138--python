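"""Distalization-efficiency metrics and the comparison report.

The staged scenario prescribes 2.0 mm of distal movement for both
premolars (teeth 4 and 5) into the space mesial of the first molar.
Efficiency of a prescribed tooth is the achieved distal crown movement as
a percentage of the prescription; anchorage loss of a molar (teeth 6, 7)
is its unwanted mesial drift as a percentage of the same prescription.
Both are clamped at zero for wrong-direction motion (magnitudes are
reported; a ``signed=True`` flag exposes the raw values).  The improvement
of one design over another is the difference of their anchorage losses in
percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aligner import TrimDesign
from .measurement import (QUANTITIES, DisplacementRecord, build_local_frame,
                          decompose_motion, tooth_landmarks)

PRESCRIBED_TEETH = (4, 5)
ANCHOR_TEETH = (6, 7)
DESIGN_ORDER = (TrimDesign.CON, TrimDesign.SMHW, TrimDesign.MHW)


def efficiency(md_displacement: float, prescribed: float,
               signed: bool = False) -> float:
    """Achieved distal movement as percent of the prescription.

    ``md_displacement`` follows the reporting sign convention (mesial +,
    distal -), so distal movement contributes with a minus sign.
    """
    if prescribed <= 0:
        raise ValueError("prescribed movement must be positive")
    value = 100.0 * (-md_displacement) / prescribed
    return value if signed else max(0.0, value)


def anchorage_loss(md_displacement: float, prescribed: float,
                   signed: bool = False) -> float:
    """Unwanted mesial drift as percent of the prescription."""
    if prescribed <= 0:
        raise ValueError("prescribed movement must be positive")
    value = 100.0 * md_displacement / prescribed
    return value if signed else max(0.0, value)


def improvement(loss_a: float, loss_b: float) -> float:
    """Anchorage-loss reduction of design b over design a, percentage points."""
    return loss_a - loss_b


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class EfficiencyReport:
    """Joint comparison report across trim designs."""

    records: dict                 # design value -> {tooth -> DisplacementRecord}
    space_closed_step: dict       # design value -> int
    prescribed: float = 2.0
    metrics: pd.DataFrame = field(default=None)
    wide_table: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.metrics is None:
            self.metrics = self._build_metrics()
        if self.wide_table is None:
            self.wide_table = self._build_wide_table()

    def _build_metrics(self) -> pd.DataFrame:
        rows = []
        for design in [d.value for d in DESIGN_ORDER if d.value in self.records]:
            recs = self.records[design]
            for tooth in sorted(recs):
                md = recs[tooth].md_displacement
                row = {"design": design, "tooth": tooth,
                       "md_displacement": md,
                       "space_closed_step": self.space_closed_step.get(design)}
                if tooth in PRESCRIBED_TEETH:
                    row["efficiency_pct"] = efficiency(md, self.prescribed)
                if tooth in ANCHOR_TEETH:
                    row["anchorage_loss_pct"] = anchorage_loss(md, self.prescribed)
                rows.append(row)
        return pd.DataFrame(rows)

    def _build_wide_table(self) -> pd.DataFrame:
        """Rows: quantity x design, columns: teeth 1-7 (the published layout)."""
        rows = []
        for quantity in QUANTITIES:
            for design in [d.value for d in DESIGN_ORDER
                           if d.value in self.records]:
                recs = self.records[design]
                row = {"quantity": quantity, "design": design}
                for tooth in range(1, 8):
                    row[str(tooth)] = (recs[tooth].as_dict()[quantity]
                                       if tooth in recs else np.nan)
                rows.append(row)
        return pd.DataFrame(rows)

    def design_metric(self, design, tooth: int, column: str) -> float:
        design = TrimDesign.parse(design).value
        df = self.metrics
        sel = df[(df["design"] == design) & (df["tooth"] == tooth)]
        return float(sel[column].iloc[0])

    def molar_improvement(self, design_a="con", design_b="mhw",
                          tooth: int = 6) -> float:
        return improvement(
            self.design_metric(design_a, tooth, "anchorage_loss_pct"),
            self.design_metric(design_b, tooth, "anchorage_loss_pct"))

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "wide": outdir / "report_table.csv",
            "metrics": outdir / "report_metrics.csv",
            "json": outdir / "report.json",
        }
        self.wide_table.to_csv(paths["wide"], index=False,
                               float_format="%.6f", lineterminator="\n")
        self.metrics.to_csv(paths["metrics"], index=False,
                            float_format="%.6f", lineterminator="\n")
        payload = {
            "prescribed_mm": self.prescribed,
            "space_closed_step": self.space_closed_step,
            "designs": {
                design: {str(t): recs[t].as_dict() for t in sorted(recs)}
                for design, recs in self.records.items()},
        }
        import json

        paths["json"].write_text(json.dumps(payload, indent=2, sort_keys=True))
        return paths


def records_from_trajectory(trajectory, step: int | None = None) -> dict:
    """Per-tooth displacement records of one run at a given step (default:
    the space-closed step), relative to the starting configuration."""
    if step is None:
        step = trajectory.space_closed_step
        if step is None:
            raise ValueError("trajectory never reached space closure")
    rec = trajectory.step_record(step)
    out = {}
    for tooth in trajectory.dentition.teeth:
        frame = build_local_frame(tooth, trajectory.dentition.arch)
        landmarks = tooth_landmarks(tooth)
        out[tooth.position] = decompose_motion(
            trajectory.initial_poses[tooth.position],
            rec.tooth_poses[tooth.position], frame, landmarks)
    return out


def build_report(trajectories: dict, prescribed: float = 2.0,
                 step: int | None = None) -> EfficiencyReport:
    """Comparison report from staged-run trajectories keyed by design.

    Each design contributes its records at its own space-closed step (or a
    common explicit ``step``).  A design that is missing produces a partial
    report with a warning.
    """
    present = {TrimDesign.parse(k).value: v for k, v in trajectories.items()}
    missing = [d.value for d in DESIGN_ORDER if d.value not in present]
    if missing:
        warnings.warn(f"partial report: missing designs {missing}",
                      stacklevel=2)
    records, closed = {}, {}
    for design, traj in present.items():
        records[design] = records_from_trajectory(traj, step)
        closed[design] = traj.space_closed_step
    return EfficiencyReport(records=records, space_closed_step=closed,
                            prescribed=prescribed)


def report_from_record_table(table: pd.DataFrame, space_closed_step: dict
                             | None = None, prescribed: float = 2.0
                             ) -> EfficiencyReport:
    """Report built from an already-tabulated displacement table (long
    format with columns design, tooth, and the six quantity columns) — the
    path used to check the metric arithmetic against published numbers."""
    records = {}
    for design, group in table.groupby("design"):
        recs = {}
        for _, row in group.iterrows():
            recs[int(row["tooth"])] = DisplacementRecord(
                **{q: float(row[q]) for q in QUANTITIES})
        records[TrimDesign.parse(design).value] = recs
    return EfficiencyReport(records=records,
                            space_closed_step=space_closed_step or {},
                            prescribed=prescribed)


def plot_step_series(trajectories: dict, path) -> None:
    """Per-step mesio-distal crown displacement lines for each design
    (layout mirroring the published step charts)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(trajectories), figsize=(5 * len(trajectories), 4),
                             sharey=True, squeeze=False)
    for ax, (design, traj) in zip(axes[0], sorted(trajectories.items())):
        steps = [rec.step for rec in traj.steps]
        for tooth in traj.dentition.teeth:
            series = []
            for rec in traj.steps:
                recs = records_from_trajectory(traj, rec.step)
                series.append(recs[tooth.position].md_displacement)
            ax.plot(steps, series, label=str(tooth.position))
        ax.set_title(str(design))
        ax.set_xlabel("step")
    axes[0][0].set_ylabel("mesio-distal displacement (mm)")
    axes[0][-1].legend(title="tooth", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
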