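"""Run manifests and delimited result tables.

Every results file written by the CLI is accompanied by a JSON manifest
recording the command, a digest of the parameter configuration, scenario
digests, seeds, cohort size, software version and timestamp — enough to
re-run the computation bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import IncrementalResult, format_icer
from .engine import CohortOutcome

__all__ = ["RunManifest", "sha256_digest", "write_table", "incremental_table"]


def sha256_digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    command: str
    parameter_digest: str
    scenario_digests: dict
    seed: int
    n: int
    version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def write_table(df: pd.DataFrame, path, manifest: RunManifest | None = None) -> None:
    """Write a result table as tab-delimited text with a manifest sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        manifest.write(path.with_suffix(path.suffix + ".manifest.json"))


def incremental_table(
    result: IncrementalResult,
    intervention: CohortOutcome | None = None,
    comparator: CohortOutcome | None = None,
) -> pd.DataFrame:
    """One-row summary mirroring the published comparison-table layout.

    Costs and ICERs are rounded to integer GBP and LY/QALY to three decimals
    for display; callers needing full precision should use the dataclasses.
    """
    row = {
        "delta_cost": round(result.delta_cost),
        "delta_life_years": round(result.delta_life_years, 3),
        "delta_qalys": round(result.delta_qalys, 3),
        "programme_cost": round(result.programme_cost),
        "icer": format_icer(result.icer),
        "below_nice_threshold": result.below_nice_threshold,
    }
    if comparator is not None:
        row = {
            "comparator_cost": round(comparator.mean_cost),
            "comparator_life_years": round(comparator.mean_life_years, 2),
            "comparator_qalys": round(comparator.mean_qalys, 3),
            **row,
        }
    if intervention is not None:
        row["n"] = intervention.n
    return pd.DataFrame([row])
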