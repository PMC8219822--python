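"""End-to-end analysis: descriptives → ZOIB fit → reporting trend → power.

Writes a report bundle to an output directory: descriptive tables as
CSV, posterior summaries and the inclusion breakdown as JSON, a
human-readable text report in which every number also appears in a
machine-readable file, a proportion-by-year figure, and a run manifest.
Summary JSON is byte-stable for a fixed (data, config, seed); only the
manifest carries timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._formatting import round_half_up
from .data_model import DEFAULT_WINDOW, StudyRecord, YearWindow, to_observation
from .descriptives import (
    annual_summary,
    decade_averages,
    sample_size_medians,
    summaries_to_frame,
    women_inclusion_breakdown,
)
from .mcmc import MCMCConfig
from .power import PowerSpec, two_sample_t_power
from .trends import fit_reporting_trend
from .zoib import fit_zoib

logger = logging.getLogger(__name__)

#: paper-scale posterior schedule; `fast` swaps in the reduced test schedule
DEFAULT_MCMC = MCMCConfig()


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one artifact-producing command."""

    command: str
    config_hash: str
    seed: int
    inputs: list[str]
    outputs: list[str]
    timestamp: str
    package_version: str

    @classmethod
    def create(cls, command: str, config: dict, seed: int, inputs, outputs) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        try:
            version = metadata.version("thermorep")
        except metadata.PackageNotFoundError:
            version = "unknown"
        return cls(
            command=command,
            config_hash=digest,
            seed=seed,
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            timestamp=datetime.now(timezone.utc).isoformat(),
            package_version=version,
        )

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")
        return path


def _dump_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _plot_proportion_trend(fit, window: YearWindow, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = list(window.years)
    means = [fit.proportion_by_year[y].mean for y in years]
    lo = [fit.proportion_by_year[y].ci_low for y in years]
    hi = [fit.proportion_by_year[y].ci_high for y in years]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(years, lo, hi, alpha=0.3, label="95% credible interval")
    ax.plot(years, means, lw=2, label="posterior mean")
    ax.set_xlabel("Year")
    ax.set_ylabel("Expected proportion of women")
    ax.set_ylim(0, max(hi) * 1.2)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _text_report(desc_frame, medians, breakdown, zoib_fit, trend_fit, powers, window) -> str:
    lines = ["Representation analysis report", "=" * 32, ""]
    total_articles = int(desc_frame["articles_total"].sum())
    total_participants = int(desc_frame["participants_total"].sum())
    lines.append(f"Articles: {total_articles}; participants: {total_participants}.")
    for cat, stats in medians.items():
        lines.append(
            f"Median sample size [{cat}]: {stats['median']:g} "
            f"(IQR {stats['q1']:g}-{stats['q3']:g}, n={stats['n']})"
        )
    lines.append("")
    first, last = window.start, window.end
    p_first = zoib_fit.proportion_by_year[first]
    p_last = zoib_fit.proportion_by_year[last]
    ch = zoib_fit.annual_change
    lines.append(
        f"Expected proportion of women {first}: {100 * p_first.mean:.1f}% "
        f"[{100 * p_first.ci_low:.1f}, {100 * p_first.ci_high:.1f}]"
    )
    lines.append(
        f"Expected proportion of women {last}: {100 * p_last.mean:.1f}% "
        f"[{100 * p_last.ci_low:.1f}, {100 * p_last.ci_high:.1f}]"
    )
    lines.append(
        f"Annual change: {100 * ch.mean:.1f} [{100 * ch.ci_low:.1f}, {100 * ch.ci_high:.1f}] "
        "percentage points per year"
    )
    for name in ("b1", "a1", "c1"):
        s = zoib_fit.params[name]
        lines.append(
            f"ZOIB slope {name}: {s.mean:.2f} [{s.ci_low:.2f}, {s.ci_high:.2f}] (logit scale)"
        )
    if trend_fit is not None:
        s = trend_fit.slope
        lines.append(
            f"Orientation-reporting year slope: {s.mean:.2f} [{s.ci_low:.2f}, {s.ci_high:.2f}]"
        )
        lines.append(
            f"Articles with women not reporting orientation: "
            f"{breakdown['pct_not_reporting_orientation']}%"
        )
    lines.append("")
    for (n, d), pw in powers.items():
        lines.append(
            f"Two-sample t power at n={n}/group, d={d}: {round_half_up(100 * pw, 0):.0f}%"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ReportBundle:
    """Paths and in-memory results of one full analysis run."""

    output_dir: Path
    descriptives: pd.DataFrame
    medians: dict
    breakdown: dict | None
    zoib_fit: object
    trend_fit: object | None
    outputs: list[Path]


def run_full_analysis(
    records: Sequence[StudyRecord],
    output_dir: str | Path,
    mcmc_config: MCMCConfig = DEFAULT_MCMC,
    window: YearWindow = DEFAULT_WINDOW,
    power_specs: Sequence[PowerSpec] = (
        PowerSpec(n_per_group=6, effect_size=0.8),
        PowerSpec(n_per_group=10, effect_size=0.8),
    ),
    input_path: str | Path | None = None,
) -> ReportBundle:
    """Run every analysis stage on a study corpus and write the report bundle.

    A corpus without any women-including article still yields the
    descriptive tables and the ZOIB fit (all responses exactly zero);
    the reporting trend and inclusion breakdown are then skipped with a
    logged warning rather than failing the whole run.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "descriptives"
    try:
        summaries = annual_summary(records, window)
        frame = summaries_to_frame(summaries)
        pct = pd.DataFrame(
            [{**s.article_percentages(), **s.participant_percentages()} for s in summaries],
            index=frame.index,
        ).add_suffix("_pct")
        desc = pd.concat([frame, pct], axis=1)
        outputs.append(output_dir / "annual_summary.csv")
        desc.to_csv(outputs[-1])
        outputs.append(output_dir / "decade_averages.csv")
        decade_averages(summaries).to_csv(outputs[-1])
        medians = sample_size_medians(records)
        outputs.append(_dump_json(medians, output_dir / "sample_size_medians.json"))
        has_women = any(r.includes_women for r in records)
        breakdown = women_inclusion_breakdown(records) if has_women else None
        if breakdown is not None:
            outputs.append(_dump_json(breakdown, output_dir / "inclusion_breakdown.json"))

        stage = "zoib-fit"
        observations = [to_observation(r, window) for r in records]
        zoib_fit = fit_zoib(observations, mcmc_config, window=window)
        outputs.append(_dump_json(zoib_fit.summary_dict(), output_dir / "zoib_summary.json"))
        prop_rows = [
            {"year": y, **s.as_dict()} for y, s in zoib_fit.proportion_by_year.items()
        ]
        outputs.append(output_dir / "proportion_by_year.csv")
        pd.DataFrame(prop_rows).to_csv(outputs[-1], index=False)
        outputs.append(
            _plot_proportion_trend(zoib_fit, window, output_dir / "proportion_trend.png")
        )

        stage = "reporting-trend"
        trend_fit = None
        if has_women:
            trend_fit = fit_reporting_trend(records, mcmc_config, window=window)
            outputs.append(
                _dump_json(trend_fit.summary_dict(), output_dir / "reporting_trend.json")
            )
        else:
            logger.warning("no records include women; reporting trend skipped")

        stage = "power"
        powers = {(s.n_per_group, s.effect_size): two_sample_t_power(s) for s in power_specs}
        outputs.append(output_dir / "power.csv")
        pd.DataFrame(
            [
                {"n_per_group": n, "effect_size": d, "power": pw}
                for (n, d), pw in powers.items()
            ]
        ).to_csv(outputs[-1], index=False)

        stage = "report"
        text = _text_report(desc, medians, breakdown, zoib_fit, trend_fit, powers, window)
        outputs.append(output_dir / "report.txt")
        outputs[-1].write_text(text, encoding="utf-8")
    except Exception as exc:
        for p in outputs:  # remove partial bundle so failed runs leave no half-results
            p.unlink(missing_ok=True)
        raise RuntimeError(f"analysis stage '{stage}' failed: {exc}") from exc

    manifest = RunManifest.create(
        command="run-all",
        config={"mcmc": asdict(mcmc_config), "window": asdict(window)},
        seed=mcmc_config.seed,
        inputs=[input_path] if input_path else [],
        outputs=outputs,
    )
    outputs.append(manifest.write(output_dir / "manifest.json"))
    return ReportBundle(
        output_dir=output_dir,
        descriptives=desc,
        medians=medians,
        breakdown=breakdown,
        zoib_fit=zoib_fit,
        trend_fit=trend_fit,
        outputs=outputs,
    )
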