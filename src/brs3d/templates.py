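"""Template-library construction: diversity selection over a self-shape-similarity matrix.

The descriptor's axes are an ordered library of template conformers picked to
cover the shape space of a candidate ligand pool.  Candidates are compared
all-against-all with rigid superposition, the similarity matrix is converted
to distances (1 - s), clustered hierarchically (average linkage) and one
medoid per cluster is kept.  A MaxMin picker is available as an alternative
selection rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .shape import Molecule3D, read_sdf, superimpose, write_sdf

__all__ = [
    "TemplateLibrary",
    "self_similarity_matrix",
    "select_diverse",
    "build_library",
]


@dataclass
class TemplateLibrary:
    """Ordered set of template conformers defining the descriptor axes."""

    templates: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [t.mol_id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise ValueError("template ids must be unique")
        if not self.templates:
            raise ValueError("template library cannot be empty")

    @property
    def k(self) -> int:
        return len(self.templates)

    @property
    def ids(self) -> list:
        return [t.mol_id for t in self.templates]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sdf(self.templates, outdir / "templates.sdf")
        meta = {"k": self.k, "ids": self.ids, "provenance": self.provenance}
        (outdir / "library.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, indir) -> "TemplateLibrary":
        indir = Path(indir)
        meta = json.loads((indir / "library.json").read_text())
        templates = read_sdf(indir / "templates.sdf")
        if [t.mol_id for t in templates] != meta["ids"]:
            raise ValueError("library metadata does not match the SDF record order")
        return cls(templates=templates, provenance=meta.get("provenance", {}))


def self_similarity_matrix(ligands: list, seed: int = 0, **superimpose_kwargs) -> np.ndarray:
    """All-against-all best superposition scores, symmetrized as (M + M.T) / 2.

    The diagonal is 1 by construction (a conformer overlaid on itself).
    """
    k = len(ligands)
    if k < 2:
        raise ValueError("need at least 2 ligands")
    m = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            m[i, j] = superimpose(
                ligands[i], ligands[j], n_poses=1, seed=seed, **superimpose_kwargs
            )[0].score
    return (m + m.T) / 2.0


def select_diverse(sim: np.ndarray, k: int, method: str = "average") -> list:
    """Pick ``k`` diverse indices from a similarity matrix.

    method "average": average-linkage hierarchical clustering of d = 1 - sim
    cut into ``k`` clusters; the medoid (maximum total within-cluster
    similarity, ties to the lowest index) of each cluster is returned.
    method "maxmin": greedy MaxMin picking starting from the global medoid.
    Output is sorted ascending and deterministic.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return list(range(n))
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)

    if method == "maxmin":
        picked = [int(np.argmax(sim.sum(axis=1)))]
        while len(picked) < k:
            d_to_picked = dist[:, picked].min(axis=1)
            d_to_picked[picked] = -1.0
            picked.append(int(np.argmax(d_to_picked)))
        return sorted(picked)
    if method != "average":
        raise ValueError(f"unknown selection method {method!r}")

    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    picks = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        within = sim[np.ix_(members, members)].sum(axis=1)
        picks.append(int(members[int(np.argmax(within))]))
    return sorted(picks)


def build_library(
    ligands: list,
    k: int = 300,
    seed: int = 0,
    method: str = "average",
    source: str | None = None,
) -> TemplateLibrary:
    """Compose self-similarity + diversity selection into a TemplateLibrary."""
    if len(ligands) < k:
        raise ValueError(f"need at least k={k} candidate ligands, got {len(ligands)}")
    if len(ligands) == k:
        picks = list(range(k))
    else:
        sim = self_similarity_matrix(ligands, seed=seed)
        picks = select_diverse(sim, k, method=method)
    id_hash = hashlib.sha256("|".join(l.mol_id for l in ligands).encode()).hexdigest()[:16]
    prov = {
        "k": k,
        "seed": int(seed),
        "method": method,
        "n_candidates": len(ligands),
        "candidate_id_hash": id_hash,
    }
    if source:
        prov["source"] = source
    return TemplateLibrary(templates=[ligands[i] for i in picks], provenance=prov)
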