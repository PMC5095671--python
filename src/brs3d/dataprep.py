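"""Curation of bioactivity tables into pairwise subtype-selectivity datasets.

Raw binding records (compound, target, qualifier, pKi) are filtered to
exactly-measured values, windowed on heavy-atom count, and replicate
measurements averaged.  For a target pair (T1, T2) the selectivity ratio is

    SR = pKi(T1) - pKi(T2),

so SR > 1 marks a T1-selective compound (>= 10-fold affinity ratio), SR < -1
a T2-selective one, and anything in between non-selective.  Regression models
use SR directly; discrimination models use only the selective rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ActivityRecord",
    "PairDataset",
    "curate_records",
    "build_pair_dataset",
    "split_train_test",
    "read_activity_table",
    "write_activity_table",
    "T1_SELECTIVE",
    "T2_SELECTIVE",
    "NONSELECTIVE",
    "TRAIN",
    "TEST",
]

logger = logging.getLogger(__name__)

QUALIFIERS = ("=", ">", "<", "~")
T1_SELECTIVE = "T1_SELECTIVE"
T2_SELECTIVE = "T2_SELECTIVE"
NONSELECTIVE = "NONSELECTIVE"
TRAIN = "TRAIN"
TEST = "TEST"
UNASSIGNED = ""


@dataclass(frozen=True)
class ActivityRecord:
    """One curated or raw binding measurement (pKi = -log10 Ki)."""

    compound_id: str
    target_id: str
    qualifier: str
    pki: float
    heavy_atom_count: int

    def __post_init__(self):
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"invalid qualifier {self.qualifier!r}")
        if self.heavy_atom_count < 1:
            raise ValueError("heavy_atom_count must be >= 1")
        if self.qualifier == "=" and not np.isfinite(self.pki):
            raise ValueError(
                f"{self.compound_id}/{self.target_id}: non-finite pKi on an exact record"
            )


@dataclass
class PairDataset:
    """Pairwise selectivity table for two targets.

    ``frame`` columns: compound_id, pki_t1, pki_t2, sr, label, split.
    """

    pair_name: str
    t1: str
    t2: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        f = self.frame
        required = {"compound_id", "pki_t1", "pki_t2", "sr", "label", "split"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"pair dataset missing columns: {sorted(missing)}")
        if not np.allclose(f["sr"], f["pki_t1"] - f["pki_t2"]):
            raise ValueError("sr column inconsistent with pKi difference")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def selective(self) -> pd.DataFrame:
        """Rows with |SR| > 1 — the discrimination subset."""
        return self.frame[self.frame["label"] != NONSELECTIVE]


def _label(sr: float) -> str:
    if sr > 1.0:
        return T1_SELECTIVE
    if sr < -1.0:
        return T2_SELECTIVE
    return NONSELECTIVE


def curate_records(
    records: list, min_heavy: int = 8, max_heavy: int = 80
) -> list:
    """Keep exact ("=") records with heavy-atom count inside the inclusive
    window, then average replicate pKi values per (compound, target)."""
    if not records:
        raise ValueError("no records supplied")
    kept = [
        r
        for r in records
        if r.qualifier == "=" and min_heavy <= r.heavy_atom_count <= max_heavy
    ]
    if not kept:
        logger.warning("curation removed every record")
        return []
    groups: dict = {}
    for r in kept:
        groups.setdefault((r.compound_id, r.target_id), []).append(r)
    out = []
    for (_, _), rs in sorted(groups.items()):
        out.append(replace(rs[0], pki=float(np.mean([r.pki for r in rs]))))
    return out


def build_pair_dataset(curated: list, t1: str, t2: str, pair_name: str | None = None) -> PairDataset:
    """Rows are exactly the compounds measured against both targets."""
    seen = set()
    for r in curated:
        key = (r.compound_id, r.target_id)
        if key in seen:
            raise ValueError(f"duplicate record for {key}; run curate_records first")
        seen.add(key)
    by_t1 = {r.compound_id: r.pki for r in curated if r.target_id == t1}
    by_t2 = {r.compound_id: r.pki for r in curated if r.target_id == t2}
    shared = sorted(set(by_t1) & set(by_t2))
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} compounds measured against both {t1} and {t2}"
        )
    rows = []
    for cid in shared:
        sr = by_t1[cid] - by_t2[cid]
        rows.append(
            {
                "compound_id": cid,
                "pki_t1": by_t1[cid],
                "pki_t2": by_t2[cid],
                "sr": sr,
                "label": _label(sr),
                "split": UNASSIGNED,
            }
        )
    return PairDataset(
        pair_name=pair_name or f"{t1}-{t2}",
        t1=t1,
        t2=t2,
        frame=pd.DataFrame(rows),
    )


def split_train_test(ds: PairDataset, test_fraction: float = 0.2, seed: int = 0) -> PairDataset:
    """Randomly assign rows to TRAIN/TEST; |TEST| = round(n * test_fraction)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(ds)
    n_test = int(np.floor(n * test_fraction + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.full(n, TRAIN, dtype=object)
    split[order[:n_test]] = TEST
    frame = ds.frame.copy()
    frame["split"] = split
    return PairDataset(pair_name=ds.pair_name, t1=ds.t1, t2=ds.t2, frame=frame)


def read_activity_table(path) -> list:
    """Delimited text (comma or tab sniffed from the header) with columns
    compound_id, target_id, qualifier, pki and optionally heavy_atom_count."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str, "target_id": str})
    required = {"compound_id", "target_id", "qualifier", "pki"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "heavy_atom_count" not in df.columns:
        df["heavy_atom_count"] = 1
    return [
        ActivityRecord(
            compound_id=row.compound_id,
            target_id=row.target_id,
            qualifier=str(row.qualifier),
            pki=float(row.pki),
            heavy_atom_count=int(row.heavy_atom_count),
        )
        for row in df.itertuples()
    ]


def write_activity_table(records: list, path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "target_id": r.target_id,
                "qualifier": r.qualifier,
                "pki": r.pki,
                "heavy_atom_count": r.heavy_atom_count,
            }
            for r in records
        ]
    ).to_csv(path, sep=sep, index=False)
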