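"""The shape-similarity-profile descriptor.

A molecule's descriptor is the vector of best superposition scores against
every template in an ordered library: element j is the highest of the pose
scores returned by superimposing the molecule onto template j.  With the
default 300-template library this yields a 300-dimensional profile whose
entries all lie in [0, 1]; columns are named BRS001, BRS002, ...
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, TransformerMixin

from .shape import Molecule3D, superimpose
from .templates import TemplateLibrary, build_library

__all__ = [
    "SimilarityProfile",
    "SimilarityProfiler",
    "compute_profile",
    "profile_batch",
    "brs_columns",
]

logger = logging.getLogger(__name__)


def brs_columns(k: int) -> list:
    """Positional feature names BRS001..BRSk (width grows past 999 axes)."""
    width = max(3, len(str(k)))
    return [f"BRS{i:0{width}d}" for i in range(1, k + 1)]


@dataclass
class SimilarityProfile:
    """One molecule's profile, positionally aligned with the library order."""

    compound_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("profile values must lie in [0, 1]")


def compute_profile(
    mol: Molecule3D,
    library: TemplateLibrary,
    n_poses: int = 10,
    seed: int = 0,
) -> SimilarityProfile:
    """Best superposition score of ``mol`` against every library template.

    A superposition failure for one template yields 0 for that element (the
    lowest similarity) with a logged warning rather than aborting the profile.
    """
    values = np.zeros(library.k)
    for j, tpl in enumerate(library.templates):
        try:
            poses = superimpose(mol, tpl, n_poses=n_poses, seed=seed)
            values[j] = poses[0].score
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning(
                "superposition of %s onto template %s failed (%s); element set to 0",
                mol.mol_id,
                tpl.mol_id,
                exc,
            )
    return SimilarityProfile(compound_id=mol.mol_id, values=values)


def profile_batch(
    mols: list,
    library: TemplateLibrary,
    n_poses: int = 10,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Profile table (one row per molecule), identical for any worker count."""
    ids = [m.mol_id for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")
    cols = brs_columns(library.k)
    if not mols:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="compound_id"))
    results = Parallel(n_jobs=n_jobs)(
        delayed(compute_profile)(m, library, n_poses=n_poses, seed=seed) for m in mols
    )
    data = np.vstack([r.values for r in results])
    return pd.DataFrame(data, index=pd.Index(ids, name="compound_id"), columns=cols)


class SimilarityProfiler(TransformerMixin, BaseEstimator):
    """Transformer from 3D molecules to shape-similarity profiles.

    Parameters
    ----------
    library : TemplateLibrary or None
        Use this library as-is; when None, ``fit`` builds one from the
        candidate ligands it is given.
    k : int
        Library size when building from candidates (the classic profile uses
        300 templates; smaller libraries trade resolution for speed).
    n_poses : int
        Poses kept per superposition; only the best contributes.
    n_jobs : int
        Parallel workers for ``transform``.
    random_state : int
        Seed for superposition starts and library construction.
    """

    def __init__(
        self,
        library: TemplateLibrary | None = None,
        k: int = 300,
        n_poses: int = 10,
        n_jobs: int = 1,
        random_state: int = 0,
    ):
        self.library = library
        self.k = k
        self.n_poses = n_poses
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: candidate ligands (ignored when a library was supplied)."""
        if self.library is not None:
            self.library_ = self.library
        else:
            self.library_ = build_library(list(X), k=self.k, seed=self.random_state)
        self.feature_names_out_ = brs_columns(self.library_.k)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "library_"):
            raise RuntimeError("SimilarityProfiler is not fitted")
        return profile_batch(
            list(X),
            self.library_,
            n_poses=self.n_poses,
            seed=self.random_state,
            n_jobs=self.n_jobs,
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_)
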