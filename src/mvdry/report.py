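"""Report writing: delimited-text tables plus a provenance summary."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .config import StudyConfig, config_hash


def write_report(results: dict[str, pd.DataFrame], out_dir: str | Path,
                 config: StudyConfig | None = None,
                 seed: int | None = None) -> Path:
    """Write each result table as CSV plus a plain-text provenance summary.

    ``results`` maps table name -> DataFrame.  The summary records the
    software version, the seed(s) used, and the config hash, so a report
    can be tied back to the exact inputs that produced it.  Returns the
    path of the summary file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"mvdry version: {__version__}"]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if config is not None:
        lines.append(f"config hash: {config_hash(config)}")
    for name, frame in results.items():
        csv_path = out / f"{name}.csv"
        frame.to_csv(csv_path, index=False)
        lines.append(f"table {name}: {len(frame)} rows -> {csv_path.name}")
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
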