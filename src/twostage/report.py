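"""Comparison tables across recruitment designs, sorted by total cost."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .recruitment import DesignEstimate

__all__ = ["design_table", "frame_to_markdown", "format_usd"]


def format_usd(cents: int) -> str:
    """Presentation formatting: thousands separators, exact cents when nonzero."""
    dollars, rem = divmod(cents, 100)
    return f"${dollars:,}" + (f".{rem:02d}" if rem else "")


def design_table(estimates: Mapping[str, DesignEstimate]) -> pd.DataFrame:
    """One row per labelled design, sorted by total cost then label.

    The label conventionally encodes modality and severity range (e.g.
    ``"clinical severe"``); the stable label tie-break keeps equal-cost rows
    in a deterministic order.
    """
    if not estimates:
        raise ValueError("no design estimates supplied")
    rows = []
    for label, est in estimates.items():
        rows.append({
            "design": label,
            "n_prescreen": est.n_prescreen,
            "cost_prescreen_usd": est.cost_prescreen_usd,
            "n_mri": est.n_mri,
            "cost_mri_usd": est.cost_mri_usd,
            "cost_total_usd": est.cost_total_usd,
            "p_prescreen": est.inputs.p_prescreen,
            "p_wmh_given_positive": est.inputs.p_wmh_given_positive,
            "attrition": est.inputs.attrition,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["cost_total_usd", "design"],
                          kind="stable").reset_index(drop=True)


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown rendering of a table."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)
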