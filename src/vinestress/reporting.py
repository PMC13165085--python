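"""Trial orchestration: run the whole pipeline from a config and summarize.

``run_trial`` takes a YAML/JSON trial configuration, simulates (or loads)
the spectrum table, preprocesses it, monitors every plant, computes group
change-day summaries, the wavelength-importance loadings table, and the
stem-potential reference statistics, and writes everything to a
deterministic artifact directory.  Figures are optional so the core
pipeline stays headless.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .monitor import ChangeReport, monitor_trial, wavelength_importance
from .preprocess import PreprocessConfig, preprocess_table
from .refstats import comparisons_to_frame, reference_table
from .synthetic import (
    SpectralScenario,
    TrialDesign,
    design_2024,
    design_2025,
    generate_trial,
    irrigation_dose,
)
from .tables import save_table

__all__ = ["GroupSummary", "summarize_groups", "run_trial", "display_round",
           "load_config", "demo_config"]


def display_round(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed field reports.

    (Banker's rounding would print a mean change day of 4.625 as 4.62;
    reports print 4.63.)
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GroupSummary:
    """Change-day statistics of one treatment group."""

    group: str
    mean_change_day: float
    sd_change_day: float
    n_plants: int
    per_plant: dict[str, tuple[int, bool]]  # plant -> (change_day, defaulted)
    sd_defined: bool = True

    @property
    def mean_display(self) -> float:
        return display_round(self.mean_change_day)

    @property
    def sd_display(self) -> float:
        return display_round(self.sd_change_day)


def summarize_groups(
    reports: list[ChangeReport], design: TrialDesign | None = None
) -> list[GroupSummary]:
    """Arithmetic mean and sample sd of change days per treatment group.

    Raw values are preserved; 2-decimal display values are exposed as
    properties.  A single-plant group reports sd 0 with ``sd_defined``
    False.
    """
    if design is not None:
        seen = {r.plant_id for r in reports}
        missing = set(design.plants) - seen
        if missing:
            raise ValueError(f"missing change reports for plants {sorted(missing)}")
    by_group: dict[str, list[ChangeReport]] = {}
    for r in reports:
        group = r.group or (design.group_of_plant[r.plant_id] if design else "")
        by_group.setdefault(group, []).append(r)
    out = []
    for group in sorted(by_group):
        rs = by_group[group]
        days = np.array([r.change_day for r in rs], dtype=float)
        sd_defined = days.size > 1
        out.append(
            GroupSummary(
                group=group,
                mean_change_day=float(days.mean()),
                sd_change_day=float(days.std(ddof=1)) if sd_defined else 0.0,
                n_plants=len(rs),
                per_plant={r.plant_id: (r.change_day, r.defaulted) for r in rs},
                sd_defined=sd_defined,
            )
        )
    return out


def demo_config(seed: int = 0) -> dict:
    """Bundled demonstration configuration: first-campaign design,
    default stress scenario, onset on day 3."""
    return {
        "design": {"preset": "2024", "seed": seed},
        "scenario": {"stress_onset_day": 3},
        "preprocess": {"window": 11, "polyorder": 2,
                       "mean_center_scope": "per_plant_all_days"},
        "monitor": {"k": 3, "alpha": 0.01},
        "refstats": {"alpha": 0.01},
        "trim_max_wavelength": 980.0,
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "design" not in cfg:
        raise ValueError("config must be a mapping with a 'design' section")
    return cfg


def _build_design(cfg: dict) -> TrialDesign:
    d = dict(cfg)
    preset = d.pop("preset", None)
    if preset == "2024":
        base = design_2024(seed=d.pop("seed", 0))
    elif preset == "2025":
        base = design_2025(seed=d.pop("seed", 0))
    elif preset is None:
        return TrialDesign(**d)
    else:
        raise ValueError(f"unknown design preset {preset!r}")
    if "group_of_plant" in d:
        unknown = set(d["group_of_plant"]) - set(base.plants)
        if unknown:
            raise ValueError(
                f"unknown plant id(s) in group map: {sorted(unknown)}"
            )
        base.group_of_plant.update(d.pop("group_of_plant"))
    for key, val in d.items():
        if not hasattr(base, key):
            raise ValueError(f"unknown design field {key!r}")
        setattr(base, key, val)
    base.__post_init__()
    return base


def _build_scenario(cfg: dict) -> SpectralScenario:
    from .synthetic import AbsorptionFeature

    d = dict(cfg or {})
    if "absorption_features" in d:
        d["absorption_features"] = [AbsorptionFeature(**f)
                                    for f in d["absorption_features"]]
    return SpectralScenario(**d)


def run_trial(
    config: str | Path | dict,
    out_dir: str | Path,
    figures: bool = False,
) -> Path:
    """Execute the full synthetic-trial pipeline and write its artifacts.

    Writes: ``spectra.csv`` (raw simulated table), ``psi.csv``,
    ``truth.json`` (onset ground truth), ``change_report.csv`` and
    ``.json``, ``group_summary.csv``, ``loadings.csv``,
    ``reference_stats.csv`` and ``run.log``.  Rerunning with the same
    config reproduces identical numeric outputs.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = _build_design(cfg["design"])
    scenario = _build_scenario(cfg.get("scenario", {}))
    table, psi_records, onset_map = generate_trial(design, scenario)
    save_table(table, out / "spectra.csv",
               provenance=f"vinestress {__version__} seed={design.seed}")
    psi = pd.DataFrame(
        [(r.plant_id, r.group, r.day, r.psi) for r in psi_records],
        columns=["plant_id", "group", "day", "psi_MPa"],
    )
    psi.to_csv(out / "psi.csv", index=False)
    (out / "truth.json").write_text(json.dumps(onset_map, indent=1))

    cutoff = cfg.get("trim_max_wavelength")
    work = table
    if cutoff is not None:
        from .hsi_io import trim_bands

        work = trim_bands(work, float(cutoff))
    pre = preprocess_table(work, PreprocessConfig(**cfg.get("preprocess", {})))

    mon = cfg.get("monitor", {})
    reports = monitor_trial(pre, k=mon.get("k", 3), alpha=mon.get("alpha", 0.01))

    rows = []
    for r in reports:
        for d, vals in r.md2_by_pixel_by_day.items():
            rows.append(
                {
                    "plant_id": r.plant_id,
                    "group": r.group,
                    "day": d,
                    "median_md2": float(np.median(vals)),
                    "p_value": r.pvalue_by_day.get(d, float("nan")),
                    "is_change_day": d == r.change_day and not r.defaulted,
                }
            )
    pd.DataFrame(rows).to_csv(out / "change_report.csv", index=False)
    (out / "change_report.json").write_text(
        json.dumps(
            {
                r.plant_id: {
                    "group": r.group,
                    "change_day": r.change_day,
                    "defaulted": r.defaulted,
                    "p_by_day": {str(d): p for d, p in r.pvalue_by_day.items()},
                }
                for r in reports
            },
            indent=1,
        )
    )

    summaries = summarize_groups(reports, design)
    pd.DataFrame(
        [
            {
                "group": s.group,
                "mean_change_day": s.mean_display,
                "sd_change_day": s.sd_display,
                "n_plants": s.n_plants,
            }
            for s in summaries
        ]
    ).to_csv(out / "group_summary.csv", index=False)

    loadings = {}
    wl_grid = None
    for r in reports:
        if r.model is not None:
            loadings[r.plant_id] = r.model.loadings[:, 0]
            wl_grid = r.model.wavelengths
    if wl_grid is not None:
        pd.DataFrame({"wavelength_nm": wl_grid, **loadings}).to_csv(
            out / "loadings.csv", index=False
        )

    ref = reference_table(psi, alpha=cfg.get("refstats", {}).get("alpha", 0.01))
    comparisons_to_frame(ref).to_csv(out / "reference_stats.csv", index=False)

    dose = irrigation_dose(design.irrigation_minutes_per_day, design.emitter_rate, 1.0)
    stress_dose = irrigation_dose(
        design.irrigation_minutes_per_day, design.emitter_rate,
        design.stress_dose_fraction,
    )
    (out / "run.log").write_text(
        "\n".join(
            [
                f"vinestress {__version__} on python {platform.python_version()}",
                f"numpy {np.__version__}, pandas {pd.__version__}",
                f"design={design.year_label} seed={design.seed} "
                f"plants={design.n_plants} days={design.days} "
                f"pixels={design.pixels_per_plant_day}",
                f"control dose {dose} L/day, stress dose {stress_dose} L/day",
                "substreams: illumination=0 spectra=1 potentials=2 cube=3 sampling=4",
            ]
        )
        + "\n"
    )

    if figures:
        _write_figures(out, reports, summaries, wl_grid, loadings)
    return out


def _write_figures(out, reports, summaries, wl_grid, loadings) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for r in reports:
        days = list(r.md2_by_pixel_by_day)
        med = [float(np.median(v)) for v in r.md2_by_pixel_by_day.values()]
        ax.plot(days, med, marker="o", alpha=0.6,
                color="tab:red" if r.group == "stress" else "tab:blue")
    ax.set_xlabel("acquisition day")
    ax.set_ylabel("median MD$^2$ vs day-1 baseline")
    fig.savefig(out / "md2_by_day.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(
        [s.group for s in summaries],
        [s.mean_change_day for s in summaries],
        yerr=[s.sd_change_day for s in summaries],
        color=["tab:blue", "tab:red"][: len(summaries)],
    )
    ax.set_ylabel("mean change day")
    fig.savefig(out / "change_day_groups.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    if wl_grid is not None and loadings:
        fig, ax = plt.subplots(figsize=(7, 4))
        for plant, l1 in loadings.items():
            ax.plot(wl_grid, l1, alpha=0.5, lw=0.8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("PC1 loading")
        fig.savefig(out / "loadings.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
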