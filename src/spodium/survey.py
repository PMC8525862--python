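"""Aggregate survey statistics over detected spodium-bond contacts.

Produces the classification count matrix (acceptor element x donor class,
with marginals), the pie-chart fractions over residue categories, the
normalized radial/angular distribution and the Ramachandran point list.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .spb_detect import DONOR_CLASSES, SpBContact

#: residues whose side chains dominate the electron-rich partners
NAMED_RESIDUES = frozenset({"CYS", "HIS", "ASP", "GLU"})

FRACTION_CATEGORIES = (
    "CYS/HIS/ASP/GLU residues",
    "other amino acids",
    "water",
    "nonprotein ligands",
)

_ELEMENT_ROWS = ("N", "O", "S")


@dataclass
class SurveySummary:
    """Aggregated contact statistics."""

    counts: pd.DataFrame  # element rows x donor-class columns, with margins
    fractions: Dict[str, float]  # category -> percentage
    radial_hist: Tuple[np.ndarray, np.ndarray, np.ndarray]  # H, r_edges, t_edges
    rama_points: List[Tuple[float, float, str]] = field(default_factory=list)

    @property
    def total_contacts(self) -> int:
        return int(self.counts.loc["total", "total"])


def _fraction_category(contact: SpBContact) -> str:
    if contact.donor_class == "water":
        return "water"
    if contact.donor_class == "ligand":
        return "nonprotein ligands"
    if contact.acceptor.residue_name in NAMED_RESIDUES:
        return "CYS/HIS/ASP/GLU residues"
    return "other amino acids"


def summarize(
    contacts: Sequence[SpBContact],
    r_hat_bin: float = 0.05,
    theta_bin: float = 5.0,
    r_hat_range: Tuple[float, float] = (0.5, 2.0),
    theta_range: Tuple[float, float] = (140.0, 180.0),
) -> SurveySummary:
    """Tally contacts into the survey's summary statistics.

    The (r_hat, theta) histogram defaults to 0.05 x 5 degree bins, fine
    enough to resolve the density maximum a few tenths of an Angstrom
    beyond the van der Waals sum.
    """
    counts = pd.DataFrame(
        0, index=list(_ELEMENT_ROWS), columns=list(DONOR_CLASSES), dtype=int
    )
    cat_counts = {c: 0 for c in FRACTION_CATEGORIES}
    r_vals, t_vals = [], []
    rama: List[Tuple[float, float, str]] = []
    for c in contacts:
        el = c.acceptor.element
        if el in counts.index:
            counts.loc[el, c.donor_class] += 1
        cat_counts[_fraction_category(c)] += 1
        r_vals.append(c.r_hat)
        t_vals.append(c.theta)
        if c.phi is not None and c.psi is not None:
            rama.append((c.phi, c.psi, c.ss))

    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)

    total = sum(cat_counts.values())
    if total:
        fractions = {k: 100.0 * v / total for k, v in cat_counts.items()}
    else:
        fractions = {k: 0.0 for k in cat_counts}

    r_edges = np.arange(r_hat_range[0], r_hat_range[1] + r_hat_bin / 2, r_hat_bin)
    t_edges = np.arange(theta_range[0], theta_range[1] + theta_bin / 2, theta_bin)
    if r_vals:
        H, r_edges, t_edges = np.histogram2d(
            r_vals, t_vals, bins=(r_edges, t_edges)
        )
    else:
        H = np.zeros((len(r_edges) - 1, len(t_edges) - 1))
    return SurveySummary(
        counts=counts,
        fractions=fractions,
        radial_hist=(H, r_edges, t_edges),
        rama_points=rama,
    )


def write_summary(summary: SurveySummary, counts_path, json_path) -> None:
    """Write the count matrix as TSV and everything else as JSON."""
    summary.counts.to_csv(counts_path, sep="\t")
    H, r_edges, t_edges = summary.radial_hist
    payload = {
        "total_contacts": summary.total_contacts,
        "fractions_percent": summary.fractions,
        "radial_hist": {
            "counts": H.tolist(),
            "r_hat_edges": r_edges.tolist(),
            "theta_edges": t_edges.tolist(),
        },
        "rama_points": [
            {"phi": p, "psi": s, "ss_class": ss} for p, s, ss in summary.rama_points
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def plot_summary(summary: SurveySummary, out_prefix: str) -> List[str]:
    """Optional pie / radial-distribution / Ramachandran plots (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots()
    labels = [k for k, v in summary.fractions.items() if v > 0]
    values = [summary.fractions[k] for k in labels]
    if values:
        ax.pie(values, labels=labels, autopct="%.0f%%")
    ax.set_title("Electron-rich partners of Zn spodium bonds")
    path = f"{out_prefix}_partners_pie.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    H, r_edges, t_edges = summary.radial_hist
    fig, ax = plt.subplots()
    mesh = ax.pcolormesh(r_edges, t_edges, H.T, cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="contacts")
    ax.set_xlabel(r"$\hat{r}$ = d / (vdW sum)")
    ax.set_ylabel(r"$\theta$ (deg)")
    path = f"{out_prefix}_radial.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots()
    if summary.rama_points:
        phis, psis, _ = zip(*summary.rama_points)
        ax.scatter(phis, psis, s=4, alpha=0.5)
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel(r"$\psi$ (deg)")
    path = f"{out_prefix}_ramachandran.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
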