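"""Per-sample diagnostic reports and vulnerability-map export.

``annotate`` composes the full pipeline — bulk BRCAness classification,
CYT-to-C1QA ratio, C2C transform, vulnerability score and optional
signature scoring — into one :class:`SampleReport` per sample.  Reports
serialize to JSON deterministically (sorted keys, no timestamps) so two
runs on identical inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifier import BRCAnessClassifier, classify_bulk
from .immune import score_signatures
from .matrix import ExpressionMatrix, GeneSet
from .vulnerability import (
    C2CParams,
    VulnerabilityWeights,
    compute_vulnerability,
    vulnerability_map,
)

__all__ = ["SampleReport", "annotate", "reports_to_frame", "render_map"]


@dataclass
class SampleReport:
    sample_id: str
    brcaness_probability: float
    brcaness_label: str
    cyt: float
    c1qa: float
    ratio: float | None
    c2c: float | None
    vulnerability_score: float | None
    signature_scores: dict[str, float] = field(default_factory=dict)
    phenotype: str | None = None
    tool_version: str = __version__
    seed: int | None = None
    input_checksums: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # NaN is not valid JSON; undefined quantities serialize as null
        for k, v in d.items():
            if isinstance(v, float) and np.isnan(v):
                d[k] = None
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _checksum(expr: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update("\t".join(expr.gene_ids).encode())
    h.update("\t".join(expr.sample_ids).encode())
    h.update(np.ascontiguousarray(expr.values).tobytes())
    return h.hexdigest()


def annotate(
    expr: ExpressionMatrix,
    model: BRCAnessClassifier,
    gene_sets: Sequence[GeneSet] | None = None,
    c2c_params: C2CParams = C2CParams(),
    weights: VulnerabilityWeights = VulnerabilityWeights(),
    seed: int | None = None,
    impute_missing: str | None = None,
) -> list[SampleReport]:
    """One diagnostic report per sample from expression and a trained model."""
    calls = classify_bulk(model, expr, impute_missing=impute_missing)
    vuln = compute_vulnerability(
        expr, calls["brcaness_probability"], params=c2c_params, weights=weights
    )
    sig_scores = None
    if gene_sets:
        sig_scores = score_signatures(expr, list(gene_sets))
    checksum = {"expression": _checksum(expr)}

    reports = []
    for s in expr.sample_ids:
        row = vuln.loc[s]
        scores = (
            {name: float(sig_scores.scores.loc[name, s]) for name in sig_scores.signature_names}
            if sig_scores is not None
            else {}
        )
        reports.append(
            SampleReport(
                sample_id=s,
                brcaness_probability=float(calls.loc[s, "brcaness_probability"]),
                brcaness_label=str(calls.loc[s, "brcaness_label"]),
                cyt=float(row["cyt"]),
                c1qa=float(row["c1qa"]),
                ratio=float(row["ratio"]),
                c2c=float(row["c2c"]),
                vulnerability_score=float(row["vulnerability_score"]),
                signature_scores=scores,
                seed=seed,
                input_checksums=checksum,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[SampleReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "sample_id": r.sample_id,
            "brcaness_probability": r.brcaness_probability,
            "brcaness_label": r.brcaness_label,
            "cyt": r.cyt,
            "c1qa": r.c1qa,
            "ratio": r.ratio,
            "c2c": r.c2c,
            "vulnerability_score": r.vulnerability_score,
        }
        row.update({f"sig:{k}": v for k, v in r.signature_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def render_map(
    reports: Sequence[SampleReport],
    out_dir: str | os.PathLike,
    grid_n: int = 50,
    weights: VulnerabilityWeights = VulnerabilityWeights(),
) -> dict[str, str]:
    """Write the vulnerability map TSVs and a PNG figure; returns the paths."""
    if not reports:
        raise ValueError("render_map requires at least one report")
    os.makedirs(out_dir, exist_ok=True)
    frame = reports_to_frame(reports)
    points, lattice = vulnerability_map(frame, grid_n=grid_n, weights=weights)
    points_path = os.path.join(out_dir, "vulnerability_map.tsv")
    lattice_path = os.path.join(out_dir, "vulnerability_lattice.tsv")
    points.to_csv(points_path, sep="\t", index=False)
    lattice.to_csv(lattice_path, sep="\t", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    grid = lattice.pivot(index="y", columns="x", values="score")
    im = ax.imshow(
        grid.to_numpy(),
        origin="lower",
        extent=(0, 1, 0, 1),
        aspect="auto",
        cmap="viridis",
    )
    ax.scatter(
        points["c2c"], points["brcaness_probability"],
        c="white", edgecolors="black", s=40, zorder=3,
    )
    ax.set_xlabel("C2C")
    ax.set_ylabel("BRCAness probability")
    fig.colorbar(im, ax=ax, label="vulnerability score")
    fig_path = os.path.join(out_dir, "vulnerability_map.png")
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return {"points": points_path, "lattice": lattice_path, "figure": fig_path}
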