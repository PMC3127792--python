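"""Readers, writers and containers for maps, genotypes and phenotypes.

File dialects (all plain UTF-8 CSV/TSV):

* linkage map: ``group,marker,position_cM`` — markers ordered within group,
  strictly increasing positions;
* genotypes: one row per RIL, first column ``ril_id``, then one column per
  marker in map order with codes ``A`` (parent-1 homozygote), ``B``
  (parent-2 homozygote), ``-`` (missing);
* phenotypes (long format): ``ril_id,time,leaf,stem,root`` with times in
  days and biomass in grams; lines may have different numbers of
  measurements (progeny-specific time grids).

A convenience reader for the rotated R/qtl ``csvr`` layout (one row per
marker: ``marker,group,position,geno_1..geno_n``) is also provided.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import LinkageGroup, LinkageMap, GenotypeMatrix, _VALID_CODES

TRAITS = ("leaf", "stem", "root")


@dataclass(frozen=True)
class TraitSeries:
    """One RIL's measurement times and (leaf, stem, root) biomass vectors."""

    ril_id: str
    times: np.ndarray        # (m,), strictly increasing, days
    values: np.ndarray       # (m, 3) grams: leaf, stem, root

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != (len(t), 3):
            raise ValueError(f"RIL {self.ril_id}: values must be (n_times, 3)")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(f"RIL {self.ril_id}: times must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.times)


class PhenotypePanel:
    """Collection of :class:`TraitSeries`, one per RIL, in genotype-row order."""

    def __init__(self, series: list[TraitSeries]):
        self.series = list(series)
        if not self.series:
            raise ValueError("empty phenotype panel")
        ids = [s.ril_id for s in self.series]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ril_id in panel")
        self._grid_groups = None
        self._stack_cache: dict = {}

    def __len__(self) -> int:
        return len(self.series)

    def __getitem__(self, i: int) -> TraitSeries:
        return self.series[i]

    @property
    def ril_ids(self) -> list[str]:
        return [s.ril_id for s in self.series]

    def grid_groups(self):
        """Group lines by identical time grid -> list of (times, indices)."""
        if self._grid_groups is None:
            keys: dict[bytes, list[int]] = {}
            grids: dict[bytes, np.ndarray] = {}
            for i, s in enumerate(self.series):
                k = s.times.tobytes()
                keys.setdefault(k, []).append(i)
                grids[k] = s.times
            self._grid_groups = [(grids[k], np.asarray(v)) for k, v in keys.items()]
        return self._grid_groups

    def values_stack(self, idx) -> np.ndarray:
        """(len(idx), m, 3) stack for lines sharing one grid (cached)."""
        key = (int(idx[0]), len(idx))
        out = self._stack_cache.get(key)
        if out is None:
            out = np.stack([self.series[i].values for i in idx])
            self._stack_cache[key] = out
        return out

    def pooled_times(self) -> np.ndarray:
        return np.unique(np.concatenate([s.times for s in self.series]))

    def permuted(self, order) -> "PhenotypePanel":
        """Reassign trait series to lines in permuted order (ids keep row order).

        Used by the permutation-null machinery: phenotype vectors are
        shuffled against genotype rows while each series keeps its own
        time grid.
        """
        order = np.asarray(order)
        out = [
            TraitSeries(ril_id=self.series[i].ril_id,
                        times=self.series[p].times,
                        values=self.series[p].values)
            for i, p in enumerate(order)
        ]
        return PhenotypePanel(out)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.series:
            h.update(s.ril_id.encode())
            h.update(s.times.tobytes())
            h.update(np.ascontiguousarray(s.values).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for t, (l, st, r) in zip(s.times, s.values):
                rows.append((s.ril_id, t, l, st, r))
        return pd.DataFrame(rows, columns=["ril_id", "time", *TRAITS])


def read_phenotypes(path, known_ids=None, allow_negative: bool = False) -> PhenotypePanel:
    """Read a long-format phenotype CSV into a validated panel.

    Errors carry 1-based data-row numbers. Negative biomass is rejected
    unless ``allow_negative`` is set (simulated high-noise phenotypes can
    legitimately dip below zero).
    """
    df = pd.read_csv(path, dtype={"ril_id": str})
    required = ["ril_id", "time", *TRAITS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time", *TRAITS):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = pd.to_numeric(df[col])
    if df[list(TRAITS)].isna().any().any():
        row = int(df[list(TRAITS)].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: missing biomass value at data row {row}")
    if not allow_negative:
        neg = (df[list(TRAITS)] < 0).any(axis=1)
        if neg.any():
            row = int(neg.idxmax()) + 1
            raise ValueError(f"{path}: negative biomass at data row {row}")
    dup = df.duplicated(subset=["ril_id", "time"])
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise ValueError(f"{path}: duplicated (ril_id, time) at data row {row}")
    if known_ids is not None:
        known = set(known_ids)
        unknown = ~df["ril_id"].isin(known)
        if unknown.any():
            row = int(unknown.idxmax()) + 1
            raise ValueError(
                f"{path}: unknown ril_id {df['ril_id'][unknown.idxmax()]!r} at data row {row}"
            )
    series = []
    for rid, grp in df.groupby("ril_id", sort=False):
        grp = grp.sort_values("time")
        series.append(TraitSeries(rid, grp["time"].to_numpy(), grp[list(TRAITS)].to_numpy()))
    return PhenotypePanel(series)


def write_phenotypes(panel: PhenotypePanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path, dtype={"group": str, "marker": str})
    required = ["group", "marker", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    groups = []
    for name, grp in df.groupby("group", sort=False):
        groups.append(LinkageGroup(str(name), tuple(grp["marker"]), grp["position_cM"].to_numpy(float)))
    return LinkageMap(tuple(groups))


def write_map(linkage_map: LinkageMap, path) -> None:
    rows = [(g.name, m, p) for g in linkage_map.groups for m, p in zip(g.markers, g.positions)]
    pd.DataFrame(rows, columns=["group", "marker", "position_cM"]).to_csv(path, index=False)


def read_genotypes(path, linkage_map: LinkageMap | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str)
    if linkage_map is not None:
        expected = linkage_map.marker_names
        if list(df.columns) != expected:
            raise ValueError(f"{path}: marker columns do not match linkage-map order")
    codes = df.to_numpy(dtype="U1")
    bad = set(np.unique(codes)) - _VALID_CODES
    if bad:
        raise ValueError(f"{path}: unknown genotype codes {sorted(bad)}")
    return GenotypeMatrix(ril_ids=tuple(str(i) for i in df.index), codes=codes)


def write_genotypes(geno: GenotypeMatrix, linkage_map: LinkageMap, path) -> None:
    df = pd.DataFrame(geno.codes, index=list(geno.ril_ids), columns=linkage_map.marker_names)
    df.index.name = "ril_id"
    df.to_csv(path)


def read_rqtl_csvr(path) -> tuple[LinkageMap, GenotypeMatrix]:
    """Read a rotated R/qtl-style CSV: marker,group,position,geno_1..geno_n."""
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    marker_col, group_col, pos_col = cols[:3]
    ril_ids = tuple(cols[3:])
    groups = []
    for name, grp in df.groupby(group_col, sort=False):
        groups.append(LinkageGroup(str(name), tuple(grp[marker_col]), grp[pos_col].to_numpy(float)))
    lmap = LinkageMap(tuple(groups))
    codes = df[list(ril_ids)].to_numpy(dtype="U1").T  # rotate to RIL x marker
    return lmap, GenotypeMatrix(ril_ids=ril_ids, codes=codes)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
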