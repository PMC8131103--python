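"""Summary statistics over cytoneme snapshots.

Mean length, established-interaction counts, the pooled length-interaction
Pearson correlation, bundle identification and the bundling index
(minimum length within a bundle x number of member cytonemes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .cytoneme_sim import CytonemeSnapshot

__all__ = [
    "BundleReport",
    "mean_length",
    "interaction_count",
    "length_interaction_correlation",
    "find_bundles",
    "bundling_summary",
    "MIN_BUNDLE_CONTACTS",
]

#: a pair of cytonemes belongs to the same bundle when they form more than
#: three pairwise contacts, i.e. at least this many
MIN_BUNDLE_CONTACTS = 4


@dataclass
class BundleReport:
    """Bundles (disjoint id sets of size >= 2) and their bundling indices."""

    bundles: list[frozenset[int]]
    indices: list[int]  # per bundle: min length in bundle x bundle size
    singular_count: int
    n_total: int
    proportions: dict[int, float] = field(default_factory=dict)

    @property
    def bundled_count(self) -> int:
        return sum(len(b) for b in self.bundles)


def mean_length(snapshots: Sequence[CytonemeSnapshot]) -> tuple[float, float]:
    """Mean and SD of the per-snapshot average cytoneme length."""
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    means = np.array([s.mean_length for s in snapshots])
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return float(means.mean()), sd


def interaction_count(snapshot: CytonemeSnapshot) -> int:
    """Total established pairwise segment interactions in one snapshot."""
    return snapshot.total_contacts


def length_interaction_correlation(snapshots: Sequence[CytonemeSnapshot]) -> float:
    """Pearson r between length and per-cytoneme contact count.

    Individual cytonemes are pooled across all snapshots; each cytoneme in
    each snapshot is one observation.
    """
    lengths = np.concatenate([s.lengths for s in snapshots]).astype(float)
    counts = np.concatenate([s.contact_counts for s in snapshots]).astype(float)
    if len(lengths) < 2 or np.std(lengths) == 0 or np.std(counts) == 0:
        raise ValueError("correlation undefined: fewer than 2 points or zero variance")
    r, _ = stats.pearsonr(lengths, counts)
    return float(r)


def find_bundles(
    snapshot: CytonemeSnapshot, min_contacts: int = MIN_BUNDLE_CONTACTS
) -> BundleReport:
    """Identify cytoneme bundles in one snapshot.

    Build a graph with an edge between two cytonemes when their established
    pairwise contacts number at least ``min_contacts``; bundles are the
    connected components of size >= 2.  The bundling index of a bundle is the
    minimum member length times the member count.
    """
    n = len(snapshot.lengths)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (i, j), c in snapshot.pair_counts.items():
        if c >= min_contacts:
            g.add_edge(i, j)
    bundles = []
    indices = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            bundles.append(frozenset(comp))
            indices.append(int(min(snapshot.lengths[k] for k in comp)) * len(comp))
    bundled = sum(len(b) for b in bundles)
    sizes: dict[int, float] = {1: (n - bundled) / n if n else 0.0}
    for b in bundles:
        sizes[len(b)] = sizes.get(len(b), 0.0) + len(b) / n
    return BundleReport(
        bundles=bundles,
        indices=indices,
        singular_count=n - bundled,
        n_total=n,
        proportions=sizes,
    )


def bundling_summary(
    snapshots_by_control: dict[float, Sequence[CytonemeSnapshot]],
    min_contacts: int = MIN_BUNDLE_CONTACTS,
):
    """Bundling-index summary across a swept control parameter (E_ii).

    For each control value, bundling indices of all bundles found in all
    snapshots are pooled; snapshots with no bundle contribute an index of 0
    so sparse regimes average near zero.  Returns a
    :class:`~adhesim.pattern_metrics.SweepResult`.
    """
    from .pattern_metrics import SweepResult

    controls = sorted(snapshots_by_control)
    rows = []
    for c in controls:
        vals: list[float] = []
        for s in snapshots_by_control[c]:
            rep = find_bundles(s, min_contacts)
            vals.extend(rep.indices if rep.indices else [0.0])
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "control": c,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n": len(arr),
            }
        )
    return SweepResult(control_values=controls, records=rows, transition=None)
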