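"""Result tables, JSON export, and the run manifest.

Monetary values are carried at full precision internally; the CSV rounds to
2 decimals and the summary rows display integers (half-up), matching the
presentation of the source tables. CSVs use RFC-4180 quoting and no
thousands separators.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .core import CBAResult, ScenarioError
from .parameters import BANDS

_BAND_HEADERS = {"under5": "<5", "age5to14": "5-14", "age15plus": ">=15"}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Display rounding: round half away from zero at ``ndigits``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunManifest:
    """Record of one CLI/library run: inputs, seeds, and produced files."""

    config_path: str | None = None
    scenario: str | None = None
    seed: int | None = None
    tool_version: str = __version__
    outputs: list[str] = field(default_factory=list)
    started: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def add(self, path: Path) -> Path:
        self.outputs.append(str(path))
        return path

    def write(self, out_dir: Path) -> Path:
        for f in self.outputs:
            if not Path(f).exists():
                raise FileNotFoundError(f"manifest lists missing output: {f}")
        payload = {
            "config_path": self.config_path,
            "scenario": self.scenario,
            "seed": self.seed,
            "tool_version": self.tool_version,
            "outputs": self.outputs,
            "started": self.started,
            "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))
        return path


def result_table(result: CBAResult) -> pd.DataFrame:
    """Benefit/cost panel as a tidy DataFrame (schema-fixed row count).

    One row per benefit item x band plus cost components and summary rows.
    """
    rows = []
    for item in result.benefits.cells:
        for band in BANDS:
            rows.append({
                "section": "benefits", "item": item,
                "age_group": _BAND_HEADERS[band.value],
                "value": result.benefits.cells[item][band],
            })
    for item in BENEFIT_SUBTOTALS:
        rows.append({
            "section": "benefits", "item": item, "age_group": "all",
            "value": BENEFIT_SUBTOTALS[item](result),
        })
    for key, value in result.costs.to_dict().items():
        rows.append({"section": "costs", "item": key, "age_group": "all", "value": value})
    for key in ("npv", "bcr", "npv_per_household", "npv_per_community"):
        rows.append({"section": "summary", "item": key, "age_group": "all",
                     "value": getattr(result, key)})
    frame = pd.DataFrame(rows)
    frame["value"] = frame["value"].map(lambda v: round_half_up(v, 2))
    return frame


BENEFIT_SUBTOTALS = {
    "morbidity_subtotal": lambda r: r.benefits.morbidity_total,
    "mortality_subtotal": lambda r: r.benefits.mortality_total,
    "accessibility_subtotal": lambda r: r.benefits.accessibility_total,
    "benefits_total": lambda r: r.benefits.grand_total,
}


def write_tables(
    result: CBAResult, out_dir: str | Path, manifest: RunManifest | None = None
) -> dict[str, Path]:
    """Write the result panel as CSV and JSON; returns the file map.

    Refuses a result whose costs are non-positive (BCR undefined) before
    touching the filesystem.
    """
    if result.costs.total_pv <= 0:
        raise ScenarioError("refusing to write tables: BCR undefined (costs <= 0)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest or RunManifest(scenario=result.scenario)

    csv_path = out / f"result_{result.scenario}.csv"
    result_table(result).to_csv(csv_path, index=False)
    json_path = out / f"result_{result.scenario}.json"
    json_path.write_text(json.dumps(result.to_dict(), indent=2))
    manifest.add(csv_path)
    manifest.add(json_path)
    manifest_path = manifest.write(out)
    return {"csv": csv_path, "json": json_path, "manifest": manifest_path}


def load_result_json(path: str | Path) -> dict:
    """Re-read a result JSON written by :func:`write_tables`."""
    return json.loads(Path(path).read_text())
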