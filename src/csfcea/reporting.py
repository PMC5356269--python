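"""Result tables and run manifests.

Currency is rendered as integer dollars and QALYs to three decimals in the
aligned-text view, matching the published table layout; CSV output keeps
full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .parameters import ParameterSet, serialize_parameters
from .sensitivity import PipelineResult

__all__ = ["render_table2", "table2_text", "RunManifest", "config_digest"]

_OUTCOME_LABELS = {
    "TP": "True-positive", "FN": "False-negative",
    "FP": "False-positive", "TN": "True-negative",
}


def render_table2(res: PipelineResult) -> pd.DataFrame:
    """Per-outcome and per-strategy lifetime discounted results.

    Four outcome rows (cost, discounted life-years, QALYs, outcome
    probability), two strategy rows, the incremental row, and the ICER.
    """
    rows = []
    probs = res.probs.as_dict()
    for key in ("TP", "FN", "FP", "TN"):
        o = res.outcomes[key]
        rows.append({
            "row": _OUTCOME_LABELS[key], "kind": "outcome",
            "cost": o.discounted_cost, "life_years": o.life_years,
            "qalys": o.discounted_qalys, "probability": probs[key],
        })
    for s in (res.do_nothing, res.biomarker):
        rows.append({"row": s.label, "kind": "strategy",
                     "cost": s.total_cost, "life_years": float("nan"),
                     "qalys": s.total_qalys, "probability": float("nan")})
    inc = res.incremental
    rows.append({"row": "incremental (biomarker vs do_nothing)", "kind": "incremental",
                 "cost": inc.delta_cost, "life_years": float("nan"),
                 "qalys": inc.delta_qalys, "probability": float("nan")})
    rows.append({"row": "ICER ($/QALY)", "kind": "icer",
                 "cost": inc.icer if inc.icer is not None else float("nan"),
                 "life_years": float("nan"), "qalys": float("nan"),
                 "probability": float("nan")})
    return pd.DataFrame(rows)


def table2_text(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`render_table2` output."""
    lines = [f"{'':42s}{'Cost ($)':>12s}{'LYs':>8s}{'QALYs':>8s}{'Prob':>8s}"]
    for _, r in df.iterrows():
        cost = "" if pd.isna(r["cost"]) else f"{r['cost']:,.0f}"
        ly = "" if pd.isna(r["life_years"]) else f"{r['life_years']:.3f}"
        q = "" if pd.isna(r["qalys"]) else f"{r['qalys']:.3f}"
        p = "" if pd.isna(r["probability"]) else f"{100 * r['probability']:.1f}%"
        lines.append(f"{r['row']:42s}{cost:>12s}{ly:>8s}{q:>8s}{p:>8s}")
    return "\n".join(lines)


def config_digest(ps: ParameterSet) -> str:
    """SHA-256 over the canonical serialized parameter set: changes iff any
    input changes."""
    blob = json.dumps(serialize_parameters(ps), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    command: str
    config_digest: str
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
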