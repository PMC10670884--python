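"""Run configuration files, output writing and run manifests.

A run configuration is a single YAML document holding the full parameter
set, the regimen list and run settings (cohort size, seed, report
window).  Because every random stream is keyed by (seed, woman, purpose),
the manifest written next to the outputs — schema version, parameter
hash, seed, cohort size, regimens — suffices to reproduce a run
bit-for-bit (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .detection import BUILTIN_REGIMENS, ScreeningRegimen, get_regimen
from .engine import CohortOutcomes, ReportWindow
from .params import SCHEMA_VERSION, ParameterSet, ValidationError
from .reporting import ComparisonReport


@dataclass
class RunConfig:
    params: ParameterSet
    regimens: list[ScreeningRegimen]
    n_women: int = 100_000
    window: ReportWindow = field(default_factory=ReportWindow)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "parameters": self.params.to_dict(),
            "regimens": [_regimen_to_dict(r) for r in self.regimens],
            "run": {
                "n_women": self.n_women,
                "window": [self.window.entry_age, self.window.horizon_age],
            },
        }


def _regimen_to_dict(r: ScreeningRegimen) -> dict:
    return {"name": r.name, "phases": [list(p) for p in r.phases],
            "participation": r.participation}


def _regimen_from_entry(entry) -> ScreeningRegimen:
    if isinstance(entry, str):
        return get_regimen(entry)
    if not isinstance(entry, dict):
        raise ValidationError("regimens", f"entry must be a name or mapping, got {type(entry).__name__}")
    allowed = {"name", "phases", "start_age", "stop_age", "interval", "participation"}
    unknown = set(entry) - allowed
    if unknown:
        raise ValidationError(f"regimens.{sorted(unknown)[0]}", "unknown regimen key")
    name = entry.get("name")
    if name is None:
        raise ValidationError("regimens.name", "missing from regimen entry")
    participation = entry.get("participation", 1.0)
    if "phases" in entry:
        phases = tuple(tuple(int(x) for x in p) for p in entry["phases"])
        return ScreeningRegimen(name=name, phases=phases, participation=participation)
    if "start_age" in entry:
        return ScreeningRegimen.uniform(name, int(entry["start_age"]),
                                        int(entry["stop_age"]), int(entry["interval"]),
                                        participation)
    return get_regimen(name)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError("config", "configuration file must contain a mapping")
    allowed = {"schema_version", "parameters", "regimens", "run"}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(sorted(unknown)[0], "unknown configuration key")
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError("schema_version", f"expected {SCHEMA_VERSION}, got {data.get('schema_version')}")
    if "parameters" not in data:
        raise ValidationError("parameters", "missing from configuration")
    params = ParameterSet.from_dict(data["parameters"])
    regimens = [_regimen_from_entry(e) for e in data.get("regimens", [])]
    run = data.get("run", {})
    unknown_run = set(run) - {"n_women", "window"}
    if unknown_run:
        raise ValidationError(f"run.{sorted(unknown_run)[0]}", "unknown run key")
    window = run.get("window", [40, 76])
    return RunConfig(params=params, regimens=regimens,
                     n_women=int(run.get("n_women", 100_000)),
                     window=ReportWindow(float(window[0]), float(window[1])))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def default_config(seed: int = 0, n_women: int = 100_000) -> RunConfig:
    from .params import make_default_params

    return RunConfig(params=make_default_params(seed),
                     regimens=list(BUILTIN_REGIMENS.values()),
                     n_women=n_women)


# ---------------------------------------------------------------------------
# Manifests and output files
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    parameter_hash: str
    seed: int
    n_women: int
    regimens: list[str]
    window: list[float]
    outputs: list[str] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION
    created_at: str = ""

    @classmethod
    def for_run(cls, params: ParameterSet, n_women: int,
                regimens: list[ScreeningRegimen], window: ReportWindow,
                seed: int | None = None) -> "RunManifest":
        return cls(parameter_hash=params.content_hash(),
                   seed=params.seed if seed is None else seed,
                   n_women=n_women, regimens=[r.name for r in regimens],
                   window=[window.entry_age, window.horizon_age],
                   created_at=datetime.now(timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def outcomes_frame(outcomes: dict[str, CohortOutcomes]) -> pd.DataFrame:
    rows = [o.to_dict() for o in outcomes.values()]
    for row in rows:
        row.pop("stage_counts", None)
        row.pop("stage_per_100k", None)
        row.pop("window", None)
    return pd.DataFrame(rows)


def mortality_frame(reports: dict[str, ComparisonReport]) -> pd.DataFrame:
    """Regimen mortality comparison: deaths, reduction, relative reduction,
    national annual averted, life years saved (one table row per regimen)."""
    return pd.DataFrame([{
        "regimen": r.regimen,
        "deaths_per_1000": round(r.deaths_per_1000, 1),
        "reduction_per_1000": round(r.reduction_per_1000, 1),
        "relative_reduction_pct": round(r.relative_reduction_pct, 1),
        "national_annual_averted": r.national_annual_averted,
        "ly_saved_per_1000": round(r.ly_saved_per_1000, 1),
    } for r in reports.values()])


def burden_frame(reports: dict[str, ComparisonReport]) -> pd.DataFrame:
    """Screens per woman, recalls, negative biopsies and both NNS values."""
    return pd.DataFrame([{
        "regimen": r.regimen,
        "screens_per_woman": round(r.screens_per_woman, 1),
        "recalls_per_1000": round(r.recalls_per_1000, 1),
        "neg_biopsies_per_1000": round(r.neg_biopsies_per_1000, 1),
        "nns_per_death": None if r.nns_per_death is None else round(r.nns_per_death, 1),
        "nns_per_ly": r.nns_per_ly,
    } for r in reports.values()])


def stage_frame(outcomes: dict[str, CohortOutcomes]) -> pd.DataFrame:
    """Stage-distribution table: one column per regimen, rows Stage 0–4,
    total cancers and the early-invasive fraction, per 100,000 women."""
    cols = {}
    for name, o in outcomes.items():
        per100k = o.stage_per_100k()
        col = {f"stage_{k}": round(v, 1) for k, v in sorted(per100k.items())}
        col["total_cancers"] = round(sum(per100k.values()), 1)
        frac = o.early_invasive_fraction
        col["early_invasive_fraction"] = round(frac, 3) if frac == frac else None
        cols[name] = col
    return pd.DataFrame(cols)


def write_outputs(outcomes: dict[str, CohortOutcomes],
                  reports: dict[str, ComparisonReport],
                  manifest: RunManifest, outdir: str | Path) -> list[Path]:
    """Write cohort outcomes, comparison tables and the manifest to ``outdir``.

    Re-running with the manifest's (parameters, seed, n, regimens)
    reproduces every file byte-for-byte except the manifest timestamp.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    _write("outcomes.json", json.dumps({k: v.to_dict() for k, v in outcomes.items()},
                                       indent=2, sort_keys=True))
    _write("outcomes.csv", outcomes_frame(outcomes).to_csv(index=False))
    if reports:
        _write("report.json", json.dumps({k: v.to_dict() for k, v in reports.items()},
                                         indent=2, sort_keys=True))
        _write("mortality_report.csv", mortality_frame(reports).to_csv(index=False))
        _write("screening_burden.csv", burden_frame(reports).to_csv(index=False))
    _write("stage_table.csv", stage_frame(outcomes).to_csv())
    manifest.outputs = [p.name for p in written]
    _write("manifest.json", manifest.to_json())
    return written
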