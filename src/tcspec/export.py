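"""Export surfaces: score CSV, heatmap PNG, per-protein histogram PNG.

Numeric CSV output uses 6 decimal places, which preserves mutation-delta
arithmetic on re-import; the heatmap uses a diverging color scale with
symmetric saturation so that strongly negative (favorable) and strongly
positive (unfavorable) scores both stand out.
"""

from __future__ import annotations

import csv

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ScoringError
from .scoring import SpecificityMatrix

PRECISION = 6


def export_csv(matrix: SpecificityMatrix, path, selection=None) -> None:
    """Write comma-delimited rows (hk_id, rr_id, score).

    ``selection`` is an optional iterable of (hk_id, rr_id) cells; the full
    matrix is exported when omitted. If a mutation is active, pass the
    mutated matrix — the export always reflects the matrix it is given.
    """
    cells = (
        [(h, r) for h in matrix.hk_ids for r in matrix.rr_ids] if selection is None
        else list(selection)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hk_id", "rr_id", "score"])
        for h, r in cells:
            writer.writerow([h, r, f"{matrix.value(h, r):.{PRECISION}f}"])


def import_csv(path) -> SpecificityMatrix:
    """Parse a full-matrix CSV written by :func:`export_csv`."""
    values = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            values[(row["hk_id"], row["rr_id"])] = float(row["score"])
    hk_ids = list(dict.fromkeys(h for h, _ in values))
    rr_ids = list(dict.fromkeys(r for _, r in values))
    scores = np.full((len(hk_ids), len(rr_ids)), np.nan)
    for (h, r), v in values.items():
        scores[hk_ids.index(h), rr_ids.index(r)] = v
    return SpecificityMatrix(hk_ids=hk_ids, rr_ids=rr_ids, scores=scores)


def export_matrix_csv(matrix: SpecificityMatrix, path) -> None:
    """Write the wide form: header = RR ids, one row per HK id."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hk_id"] + list(matrix.rr_ids))
        for h, hk_id in enumerate(matrix.hk_ids):
            writer.writerow([hk_id] + [f"{v:.{PRECISION}f}" for v in matrix.scores[h]])


def export_heatmap(matrix: SpecificityMatrix, path, title: str | None = None) -> None:
    """Render the specificity matrix as a PNG heatmap.

    Diverging scale centered at zero with symmetric saturation: negative
    (encoded specificity) in blue, positive (loss of shared attributes) in
    red.
    """
    if matrix.scores.size == 0:
        raise ScoringError("cannot render an empty matrix")
    vmax = float(np.abs(matrix.scores).max()) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.5 * len(matrix.rr_ids) + 2), max(2.5, 0.4 * len(matrix.hk_ids) + 2))
    )
    im = ax.imshow(matrix.scores, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.rr_ids)), matrix.rr_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.hk_ids)), matrix.hk_ids, fontsize=7)
    ax.set_xlabel("response regulator")
    ax.set_ylabel("histidine kinase")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="H_TCSspecific")
    fig.tight_layout()
    fig.savefig(path, dpi=150, transparent=True)
    plt.close(fig)


def export_histogram(matrix: SpecificityMatrix, protein_id: str, path) -> list:
    """Bar chart of all partner scores for one HK or RR; returns the partner
    labels in plotted order (useful for programmatic checks)."""
    if protein_id in matrix.hk_ids:
        scores = matrix.scores[matrix.hk_ids.index(protein_id), :]
        labels = list(matrix.rr_ids)
        partner_kind = "response regulator"
    elif protein_id in matrix.rr_ids:
        scores = matrix.scores[:, matrix.rr_ids.index(protein_id)]
        labels = list(matrix.hk_ids)
        partner_kind = "histidine kinase"
    else:
        raise ScoringError(f"unknown protein id {protein_id!r}")
    fig, ax = plt.subplots(figsize=(max(3.0, 0.45 * len(labels) + 2), 3.2))
    ax.bar(range(len(labels)), scores, color="#4878b0")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel("H_TCSspecific")
    ax.set_xlabel(partner_kind)
    ax.set_title(protein_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150, transparent=True)
    plt.close(fig)
    return labels
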