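"""Report assembly: combine tabular artefacts into one HTML document.

Every number in the report is read back from a CSV/JSON artefact written by
an upstream command — the report layer does no computation of its own, so
any figure in the document is traceable to a file on disk. Risks are
rendered on the 0-1 scale with percentages in parentheses. Provenance (a
hash of the run configuration plus the seed) is embedded so two reports are
identical iff their inputs were.
"""

from __future__ import annotations

import hashlib
import html as html_mod
import io
import json
from datetime import datetime, timezone
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InputError


def _fmt_risk(p: float) -> str:
    return f"{p:.3f} ({p * 100:.1f}%)"


def provenance_hash(config_text: str, seed: Optional[int]) -> str:
    h = hashlib.sha256()
    h.update(config_text.encode())
    h.update(str(seed).encode())
    return h.hexdigest()[:16]


def _decisions_section(df: pd.DataFrame) -> str:
    show = df.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f" and col not in ("expected_utility_diff",):
            show[col] = show[col].map(_fmt_risk)
        elif show[col].dtype.kind == "f":
            show[col] = show[col].map(lambda v: f"{v:.4g}")
    return ("<h2>Individual decisions under uncertainty</h2>\n"
            + show.to_html(index=False, border=0))


def _calibration_figure_svg(payload: dict) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = payload["curve"]
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(6, 7), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.08})
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    ax.plot(curve["grid"], curve["fitted"], c="C0")
    ax.fill_between(curve["grid"], curve["lower"], curve["upper"],
                    color="C0", alpha=0.25)
    ax.set_ylabel("observed risk")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    edges = np.asarray(payload["histograms"]["bin_edges"])
    mids = (edges[:-1] + edges[1:]) / 2
    w = edges[1] - edges[0]
    axh.bar(mids, payload["histograms"]["non_events"], width=w, alpha=0.6)
    axh.bar(mids, payload["histograms"]["events"], width=w, alpha=0.6)
    axh.set_xlabel("estimated risk")
    buf = io.StringIO()
    fig.savefig(buf, format="svg", bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def assemble_report(decisions_csv=None, calibration_payload_json=None,
                    config_path=None, seed: Optional[int] = None) -> str:
    """Build the HTML report from whatever artefacts are supplied.

    At least one artefact is required; missing optional ones are simply
    omitted. Returns the HTML text.
    """
    if decisions_csv is None and calibration_payload_json is None:
        raise InputError("no artefacts supplied: need at least one of "
                         "decisions CSV or calibration payload JSON")
    sections = []
    if decisions_csv is not None:
        df = pd.read_csv(decisions_csv)
        sections.append(_decisions_section(df))
    if calibration_payload_json is not None:
        with open(calibration_payload_json) as fh:
            payload = json.load(fh)
        sections.append("<h2>Calibration on evaluation data</h2>\n"
                        + _calibration_figure_svg(payload)
                        + f"<p>n = {payload['n']}, events = {payload['events']}, "
                          f"{payload['curve']['level']:.0%} pointwise band, "
                          f"smoother: "
                          f"{html_mod.escape(str(payload['smoother_meta']))}</p>")
    config_text = ""
    if config_path is not None:
        with open(config_path) as fh:
            config_text = fh.read()
    prov = provenance_hash(config_text, seed)
    head = ("<html><head><meta charset='utf-8'>"
            "<title>riskuq report</title>"
            "<style>body{font-family:sans-serif;margin:2em}"
            "table{border-collapse:collapse}"
            "td,th{padding:2px 8px;border-bottom:1px solid #ddd}</style>"
            "</head><body>\n"
            "<h1>Risk estimates and their uncertainty</h1>\n"
            f"<p>Generated {datetime.now(timezone.utc).isoformat()} | "
            f"seed: {seed} | provenance: <code>{prov}</code></p>\n")
    return head + "\n".join(sections) + "\n</body></html>\n"
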