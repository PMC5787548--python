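"""Standardized result export: TSV tables, HTML index, optional plots.

The acceptance surface is the tables; the HTML index is a navigation
convenience offering the same assessment in two orderings (grouped by
region and grouped by parameter) with yellow/red highlighting, emulating
an automatically generated result compilation.  Plots are data-complete
scatter-plus-trend figures, not pixel-specified.
"""

from __future__ import annotations

import html
from pathlib import Path

import numpy as np
import pandas as pd

from .db import NormativeDB

_HL_COLOR = {"red": "#ff9999", "yellow": "#ffff99", "none": "#ffffff"}


def export_assessment_tsv(assessment: pd.DataFrame, path) -> None:
    assessment.to_csv(path, sep="\t", index=False)


def export_fit_summary_tsv(dbase: NormativeDB, path) -> None:
    """Per-key fit summary: degree, coefficients, counts, spread, fences."""
    rows = []
    for key in sorted(dbase.entries):
        e = dbase.entries[key]
        rows.append(
            {
                "key": key.as_string(),
                "degree": e.model.degree,
                "coefficients": ";".join(repr(c) for c in e.model.coeffs),
                "n_kept": e.n_kept,
                "n_rejected_raw": e.n_rejected_raw,
                "n_rejected_residual": e.n_rejected_residual,
                "sigma_norm_all": e.sigma_norm_all,
                "sigma_norm_corrected": e.sigma_norm_corrected,
                "raw_lower": e.raw_bounds.lower,
                "raw_upper": e.raw_bounds.upper,
                "resid_lower": e.resid_bounds.lower,
                "resid_upper": e.resid_bounds.upper,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_reliability_tsv(dbase: NormativeDB, path) -> None:
    """Per-key reliability and artifact table (the data behind odds maps)."""
    rows = []
    for key in sorted(dbase.entries):
        e = dbase.entries[key]
        rows.append(
            {
                "key": key.as_string(),
                "sigma_meas": e.rel.sigma_meas,
                "n_repeat_subjects": e.rel.n_repeat_subjects,
                "n_repeat_visits": e.rel.n_repeat_visits,
                "sigma_out": e.art.sigma_out,
                "n_out": e.art.n_out,
                "p_out": e.art.p_out,
                "p_art": e.art.p_art,
                "odds": e.art.odds,
                "lower_limit": e.art.lower_limit,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_loocv_tsv(report, path) -> None:
    report.summary.to_csv(path, sep="\t", index=False)


def export_feature_vector(vector: pd.Series, path) -> None:
    """Flat numeric table plus implicit key-order manifest (the index column)."""
    vector.rename("L").to_csv(path, sep="\t", index_label="key")


def _table_html(frame: pd.DataFrame, p_col: str) -> str:
    cols = list(frame.columns)
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in cols)
    body = []
    for _, row in frame.iterrows():
        color = _HL_COLOR.get(str(row.get("highlight", "none")), "#ffffff")
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                v = "" if not np.isfinite(v) else f"{v:.4g}"
            cells.append(f"<td>{html.escape(str(v))}</td>")
        body.append(f'<tr style="background:{color}">' + "".join(cells) + "</tr>")
    return (
        "<table border='1' cellspacing='0' cellpadding='2'>"
        f"<tr>{head}</tr>" + "".join(body) + "</table>"
    )


def write_html_index(assessment: pd.DataFrame, path, title: str = "Assessment") -> None:
    """Single-page HTML index with region-ordered and parameter-ordered views."""
    frame = assessment.copy()
    parts = frame["key"].str.split("|", expand=True)
    frame.insert(1, "region", parts[0])
    frame.insert(2, "hemisphere", parts[1])
    frame.insert(3, "parameter", parts[2])
    p_col = "p_ucor" if "p_ucor" in frame.columns else "p_slope"
    by_region = frame.sort_values(["region", "hemisphere", "parameter", "variant"])
    by_param = frame.sort_values(["parameter", "region", "hemisphere", "variant"])
    doc = (
        "<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title></head><body>"
        f"<h1>{html.escape(title)}</h1>"
        "<p>Yellow: uncorrected p &lt; &alpha;; red: significant after FDR "
        "correction.</p>"
        "<h2 id='by-region'>By region</h2>" + _table_html(by_region, p_col)
        + "<h2 id='by-parameter'>By parameter</h2>" + _table_html(by_param, p_col)
        + "</body></html>"
    )
    Path(path).write_text(doc, encoding="utf-8")


def plot_key(dbase: NormativeDB, key, path, patient_point=None) -> None:
    """Scatter of normative values vs age with the fitted trend and CI band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e = dbase.entries[key]
    ages = e.residues["age"].to_numpy()
    values = e.model.predict(ages) + e.residues["residue"].to_numpy()
    grid = np.linspace(e.age_min, e.age_max, 200)
    trend = e.model.predict(grid)
    hw = e.model.ci_halfwidth(grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ages, values, "o", mfc="none", ms=4, color="0.4", label="controls")
    ax.plot(grid, trend, "-", color="C0", label="age trend")
    ax.fill_between(grid, trend - hw, trend + hw, alpha=0.25, color="C0")
    if patient_point is not None:
        age, value, err = patient_point
        ax.errorbar([age], [value], yerr=[err], fmt="o", color="C3", label="patient")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(key.parameter)
    ax.set_title(key.as_string())
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
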