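"""Report rendering: CSV/JSON serialization, parameter checksums, bar charts."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .tfa import FeasibilityReport

CSV_COLUMNS = [
    "reaction_id",
    "number",
    "dRg0_kJmol",
    "lnQ_term_kJmol",
    "Qgamma",
    "dRg_kJmol",
    "feasible",
]


def parameter_checksums() -> dict[str, str]:
    """SHA-256 of the bundled parameter tables (embedded in every report)."""
    out = {}
    for name in ("pure.csv", "binary.csv", "standard_data.csv", "pka.csv"):
        path = Path(resources.files("actipath").joinpath("data", name))
        out[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def report_to_csv(report: FeasibilityReport, path: str | Path) -> None:
    """CSV with energies rounded to 2 decimals (full precision in JSON)."""
    df = report.to_frame()[CSV_COLUMNS].copy()
    for col in ("dRg0_kJmol", "lnQ_term_kJmol", "dRg_kJmol"):
        df[col] = df[col].map(lambda v: None if v is None else round(v, 2))
    df["Qgamma"] = df["Qgamma"].map(lambda v: None if v is None else f"{v:.6g}")
    df.to_csv(path, index=False)


def report_to_json(report: FeasibilityReport, path: str | Path, seed: int | None = None) -> None:
    report.metadata.setdefault("parameter_checksums", parameter_checksums())
    if seed is not None:
        report.metadata["seed"] = seed
    Path(path).write_text(report.to_json(indent=2) + "\n")


def comparison_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("dRg_activity_kJmol", "dRg_concentration_kJmol"):
        out[col] = out[col].map(lambda v: None if v is None else round(v, 2))
    out.to_csv(path, index=False)


def bar_chart(report: FeasibilityReport, path: str | Path) -> None:
    """Simple dg bar chart per reaction (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = ["tab:green" if f else "tab:red" for f in df["feasible"].fillna(False)]
    ax.bar(df["reaction_id"], df["dRg_kJmol"], color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel(r"$\Delta^R g$ / kJ mol$^{-1}$")
    ax.set_title(f"TFA {report.label} ({report.mode}, {report.T:.2f} K, pH {report.pH})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
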