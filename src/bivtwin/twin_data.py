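"""Pair-level bivariate twin data for the four-group same-sex design.

A dataset holds one record per twin pair: zygosity (MZ/DZ), sex (F/M, same-sex
pairs only) and four phenotype values ordered (twin1.trait1, twin1.trait2,
twin2.trait1, twin2.trait2), any of which may be missing (NaN). Pairs with no
observed phenotype at all are excluded at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZYGOSITIES = ("MZ", "DZ")
SEXES = ("F", "M")
#: Canonical group order used everywhere (simulation, fitting, reporting).
GROUPS = ("MZf", "DZf", "MZm", "DZm")

#: Logical column roles of the wide CSV layout, in file order.
CSV_ROLES = ("zygosity", "sex", "t1_trait1", "t1_trait2", "t2_trait1", "t2_trait2")

DEFAULT_ZYGOSITY_CODES: Mapping[str, str] = {
    "MZ": "MZ", "DZ": "DZ", "mz": "MZ", "dz": "DZ", "1": "MZ", "2": "DZ",
}
DEFAULT_SEX_CODES: Mapping[str, str] = {
    "F": "F", "M": "M", "f": "F", "m": "M", "female": "F", "male": "M",
    "1": "F", "2": "M",
}
DEFAULT_MISSING_CODES = ("", "NA", "NaN", "nan")


class SchemaError(ValueError):
    """A required column is absent from the input file."""


def group_label(zygosity: str, sex: str) -> str:
    """Return the four-group label, e.g. ('MZ', 'F') -> 'MZf'."""
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    return zygosity + sex.lower()


@dataclass(frozen=True)
class TwinPair:
    """One same-sex twin pair with up to four observed phenotype values."""

    zygosity: str
    sex: str
    y: np.ndarray  # shape (4,), NaN encodes missing

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        y = np.asarray(self.y, dtype=float)
        if y.shape != (4,):
            raise ValueError("phenotype vector must have length 4")
        if np.all(np.isnan(y)):
            raise ValueError("twin pair with no observed phenotype")
        object.__setattr__(self, "y", y)

    @property
    def group(self) -> str:
        return group_label(self.zygosity, self.sex)


@dataclass
class TwinDataset:
    """Column-oriented collection of twin pairs.

    ``y`` is an (n_pairs, 4) float array with NaN for missing entries;
    ``zygosity`` and ``sex`` are length-n object arrays of codes.
    """

    zygosity: np.ndarray
    sex: np.ndarray
    y: np.ndarray
    trait_names: tuple[str, str] = ("trait1", "trait2")
    provenance: str = ""

    def __post_init__(self) -> None:
        self.zygosity = np.asarray(self.zygosity, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.zygosity)
        if len(self.sex) != n or self.y.shape != (n, 4):
            raise ValueError("inconsistent component lengths")
        bad_z = set(self.zygosity) - set(ZYGOSITIES)
        if bad_z:
            raise ValueError(f"unknown zygosity codes {sorted(bad_z)}")
        bad_s = set(self.sex) - set(SEXES)
        if bad_s:
            raise ValueError(f"unknown sex codes {sorted(bad_s)}")
        if n and np.any(np.all(np.isnan(self.y), axis=1)):
            raise ValueError("dataset contains pairs with no observed phenotype")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.zygosity)

    def __iter__(self) -> Iterator[TwinPair]:
        for i in range(len(self)):
            yield TwinPair(self.zygosity[i], self.sex[i], self.y[i])

    @property
    def n_pairs(self) -> int:
        return len(self)

    @property
    def groups(self) -> np.ndarray:
        """Per-pair group label array."""
        return np.array(
            [group_label(z, s) for z, s in zip(self.zygosity, self.sex)],
            dtype=object,
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[TwinPair],
        trait_names: tuple[str, str] = ("trait1", "trait2"),
        provenance: str = "",
    ) -> "TwinDataset":
        if not pairs:
            return cls(
                np.empty(0, dtype=object), np.empty(0, dtype=object),
                np.empty((0, 4)), trait_names, provenance,
            )
        return cls(
            np.array([p.zygosity for p in pairs], dtype=object),
            np.array([p.sex for p in pairs], dtype=object),
            np.vstack([p.y for p in pairs]),
            trait_names,
            provenance,
        )


def observed_count(dataset: TwinDataset) -> int:
    """Total number of non-missing phenotype entries across all pairs."""
    return int(np.sum(~np.isnan(dataset.y)))


def group_split(dataset: TwinDataset) -> dict[str, TwinDataset]:
    """Partition into the four zygosity-by-sex groups, preserving pair order."""
    labels = dataset.groups
    out: dict[str, TwinDataset] = {}
    for g in GROUPS:
        idx = labels == g
        out[g] = TwinDataset(
            dataset.zygosity[idx], dataset.sex[idx], dataset.y[idx],
            dataset.trait_names, dataset.provenance,
        )
    return out


def _decode(value: object, table: Mapping[str, str], role: str, row: int) -> str:
    key = str(value).strip()
    try:
        return table[key]
    except KeyError:
        raise ValueError(f"unknown {role} code {key!r} at row {row}") from None


def read_twin_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    zygosity_codes: Mapping[str, str] = DEFAULT_ZYGOSITY_CODES,
    sex_codes: Mapping[str, str] = DEFAULT_SEX_CODES,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    trait_names: tuple[str, str] = ("trait1", "trait2"),
) -> TwinDataset:
    """Read a wide-format twin CSV into a :class:`TwinDataset`.

    ``column_map`` maps logical roles (see :data:`CSV_ROLES`) to the file's
    column names; by default role names are taken as column names. Unparseable
    phenotype cells become missing; rows with all four phenotypes missing are
    dropped (count logged at INFO level).
    """
    column_map = dict(column_map or {r: r for r in CSV_ROLES})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role in CSV_ROLES:
        col = column_map.get(role, role)
        if col not in df.columns:
            raise SchemaError(f"column {col!r} (role {role!r}) missing from {path}")

    zyg = np.array(
        [_decode(v, zygosity_codes, "zygosity", i)
         for i, v in enumerate(df[column_map["zygosity"]])],
        dtype=object,
    )
    sex = np.array(
        [_decode(v, sex_codes, "sex", i)
         for i, v in enumerate(df[column_map["sex"]])],
        dtype=object,
    )

    missing = set(missing_codes)
    y = np.full((len(df), 4), np.nan)
    for j, role in enumerate(CSV_ROLES[2:]):
        col = df[column_map[role]]
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell in missing:
                continue
            try:
                y[i, j] = float(cell)
            except ValueError:
                logger.warning("unparseable value %r at row %d column %s; "
                               "treated as missing", cell, i, role)

    keep = ~np.all(np.isnan(y), axis=1)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d pair(s) with no observed phenotype", n_dropped)
    return TwinDataset(
        zyg[keep], sex[keep], y[keep], trait_names,
        provenance=f"read from {path}",
    )


def write_twin_csv(dataset: TwinDataset, path) -> None:
    """Write the wide CSV layout; missing entries become empty fields."""
    df = pd.DataFrame({
        "zygosity": dataset.zygosity,
        "sex": dataset.sex,
        "t1_trait1": dataset.y[:, 0],
        "t1_trait2": dataset.y[:, 1],
        "t2_trait1": dataset.y[:, 2],
        "t2_trait2": dataset.y[:, 3],
    })
    df.to_csv(path, index=False, na_rep="")
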