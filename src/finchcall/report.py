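"""Assemble a human-readable Markdown report from stage outputs.

Stage outputs are whatever the pipeline produced — DataFrames, dataclasses,
dicts, scalars.  Missing stages are marked absent rather than failing, so a
partial run still yields a report; ``strict=True`` raises instead.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import numpy as np
import pandas as pd

SECTIONS = [
    ("tutor_template", "Tutor playback template"),
    ("sessions", "Session summaries (call ratio, syllable rate)"),
    ("trend", "Developmental call-ratio trend"),
    ("learners", "Learner classification"),
    ("intracellular", "Intracellular playback statistics"),
    ("perturbation", "Call-perturbation responses during singing"),
    ("extracellular", "Extracellular population summary"),
    ("tests", "Group comparisons and mixed models"),
]


def _render(value: Any) -> str:
    if isinstance(value, pd.DataFrame):
        return value.to_markdown(index=False, floatfmt=".4f")
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        d = {
            k: v
            for k, v in dataclasses.asdict(value).items()
            if not isinstance(v, (np.ndarray, list, dict)) or np.size(v) <= 8
        }
        return "\n".join(f"- {k}: {v}" for k, v in d.items())
    if isinstance(value, Mapping):
        return "\n".join(f"- {k}: {v}" for k, v in value.items())
    if isinstance(value, (list, tuple)):
        return "\n".join(f"- {_render(v)}" for v in value)
    return str(value)


def build_report(
    stage_outputs: Mapping[str, Any],
    config: Any = None,
    seed: int | None = None,
    strict: bool = False,
) -> str:
    """One Markdown report with every computed statistic plus the config
    echo and seed; sections without outputs are marked absent."""
    lines = ["# finchcall run report", ""]
    if seed is not None:
        lines += [f"seed: {seed}", ""]
    if config is not None:
        lines += ["## Configuration", "", _render(config), ""]
    known = {key for key, _ in SECTIONS}
    for key, title in SECTIONS:
        lines += [f"## {title}", ""]
        if key in stage_outputs and stage_outputs[key] is not None:
            lines += [_render(stage_outputs[key]), ""]
        else:
            if strict:
                raise ValueError(f"missing stage output: {key}")
            lines += ["_absent_", ""]
    for key in stage_outputs:
        if key not in known:
            lines += [f"## {key}", "", _render(stage_outputs[key]), ""]
    return "\n".join(lines)
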