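"""Run summary report: packing and motility tables as a Markdown document."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["report"]

_KNOWN = {
    "chamber_table": "Chamber geometry",
    "packing_table": "Per-chamber packing",
    "packing_summary": "Packing by class",
    "motility_table": "Motility by region",
    "quench_fit": "Autofluorescence quench fit",
}


def report(outputs: dict[str, pd.DataFrame], path: str | Path | None = None,
           title: str = "nichemetry run summary") -> str:
    """Assemble tables into a deterministic Markdown document.

    ``outputs`` maps artifact names to DataFrames; at least one analysis
    output must be present.  Unknown names are included under their own
    heading; missing well-known artifacts are listed at the end so a partial
    report is still produced.
    """
    present = {k: v for k, v in outputs.items() if v is not None}
    if not present:
        raise ValueError(
            "no analysis outputs present; expected any of: "
            + ", ".join(sorted(_KNOWN))
        )
    lines = [f"# {title}", ""]
    for name in sorted(present):
        df = present[name]
        lines.append(f"## {_KNOWN.get(name, name)}")
        lines.append("")
        lines.append("```")
        lines.append(df.to_string(index=False))
        lines.append("```")
        lines.append("")
    missing = sorted(set(_KNOWN) - set(present))
    if missing:
        lines.append("## Missing artifacts")
        lines.append("")
        for m in missing:
            lines.append(f"- {m}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
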