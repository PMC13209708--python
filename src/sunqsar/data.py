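"""Compound tables, activity units, and train/test splitting.

The package models butyrylcholinesterase (BChE) inhibition, expressed as
pIC50 = -log10(IC50 in mol/L), from six ADMET-type molecular descriptors:

* ``nRot``  -- rotatable-bond count,
* ``Flex``  -- flexibility, nRot/nRig,
* ``Fsp3``  -- fraction of sp3-hybridized carbons,
* ``logD``  -- octanol/water distribution coefficient at pH 7.4,
* ``caco2`` -- log Caco-2 monolayer permeability (cm/s),
* ``PPB``   -- plasma protein binding, %.

Descriptors are treated as upstream inputs (computed elsewhere); this module
only reads, validates, converts, and splits compound tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical order of the six modeling descriptors, matching the linear model.
MODELING_DESCRIPTORS: tuple[str, ...] = ("nRot", "Flex", "Fsp3", "logD", "caco2", "PPB")

#: Units for the descriptor vocabulary ("" for counts and ratios).
DESCRIPTOR_UNITS: dict[str, str] = {
    "nRot": "",
    "Flex": "",
    "Fsp3": "",
    "logD": "log10(mol/L-octanol vs water)",
    "caco2": "log10(cm/s)",
    "PPB": "%",
}

SPLIT_LABELS = ("train", "test", "validation", "unassigned")

# Characters normalized to an ASCII hyphen-minus when parsing numbers.
_MINUS_VARIANTS = {"−", "–", "—"}


class CompoundTableError(ValueError):
    """Raised for malformed compound tables."""


@dataclass(frozen=True)
class DescriptorSchema:
    """Ordered descriptor vocabulary with units.

    The six modeling descriptors always appear first, in canonical order;
    additional descriptors (MW, TPSA, nHA, ...) may follow.
    """

    names: tuple[str, ...] = MODELING_DESCRIPTORS
    units: dict[str, str] = field(default_factory=lambda: dict(DESCRIPTOR_UNITS))

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise CompoundTableError("descriptor names must be unique")
        core = [n for n in self.names if n in MODELING_DESCRIPTORS]
        if tuple(core) != MODELING_DESCRIPTORS[: len(core)]:
            raise CompoundTableError(
                "modeling descriptors must appear in canonical order "
                f"{MODELING_DESCRIPTORS}"
            )


@dataclass
class CompoundRecord:
    """One molecule: identifier, descriptors, and optional activity.

    If ``ic50_nM`` is given and ``pic50`` is not, pIC50 is derived from it.
    If both are given they must agree to 1e-9.
    """

    id: str
    descriptors: dict[str, float] = field(default_factory=dict)
    smiles: str | None = None
    ic50_nM: float | None = None
    pic50: float | None = None
    split: str = "unassigned"
    complete: bool = True  # False when a modeling descriptor is missing

    def __post_init__(self) -> None:
        if self.split not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {self.split!r}")
        if self.ic50_nM is not None:
            if self.ic50_nM <= 0:
                raise ValueError(f"IC50 must be positive, got {self.ic50_nM}")
            derived = to_pic50(self.ic50_nM)
            if self.pic50 is None:
                self.pic50 = derived
            elif abs(self.pic50 - derived) > 1e-9:
                raise ValueError(
                    f"record {self.id!r}: pic50={self.pic50} inconsistent with "
                    f"ic50_nM={self.ic50_nM} (expected {derived})"
                )
        # Flex is defined as nRot/nRig; check when both counts are stored.
        d = self.descriptors
        if "nRot" in d and "nRig" in d and "Flex" in d and d["nRig"]:
            if abs(d["Flex"] - d["nRot"] / d["nRig"]) > 1e-3:
                raise ValueError(
                    f"record {self.id!r}: Flex={d['Flex']} != nRot/nRig="
                    f"{d['nRot'] / d['nRig']:.4f}"
                )

    def has_descriptors(self, names=MODELING_DESCRIPTORS) -> bool:
        return all(n in self.descriptors for n in names)


@dataclass
class Dataset:
    """A list of compound records sharing a descriptor schema."""

    records: list[CompoundRecord]
    schema: DescriptorSchema = field(default_factory=DescriptorSchema)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "Dataset":
        """Records carrying the given split label, as a new Dataset."""
        return Dataset([r for r in self.records if r.split == split],
                       schema=self.schema, seed=self.seed)

    def descriptor_matrix(self, names=MODELING_DESCRIPTORS) -> np.ndarray:
        """(n, k) float matrix in the requested descriptor order."""
        rows = []
        for r in self.records:
            missing = [n for n in names if n not in r.descriptors]
            if missing:
                raise CompoundTableError(
                    f"record {r.id!r} missing descriptor(s) {missing}"
                )
            rows.append([r.descriptors[n] for n in names])
        return np.asarray(rows, dtype=float)

    def response(self) -> np.ndarray:
        y = [r.pic50 for r in self.records]
        if any(v is None for v in y):
            bad = [r.id for r in self.records if r.pic50 is None]
            raise CompoundTableError(f"records without observed pIC50: {bad}")
        return np.asarray(y, dtype=float)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_frame(self, names=None) -> pd.DataFrame:
        names = list(names) if names is not None else list(self.schema.names)
        data = {"id": self.ids()}
        if any(r.smiles for r in self.records):
            data["smiles"] = [r.smiles or "" for r in self.records]
        for n in names:
            data[n] = [r.descriptors.get(n, np.nan) for r in self.records]
        if any(r.pic50 is not None for r in self.records):
            data["pIC50"] = [r.pic50 if r.pic50 is not None else np.nan
                             for r in self.records]
        data["split"] = [r.split for r in self.records]
        return pd.DataFrame(data)


def to_pic50(ic50_nM: float) -> float:
    """Convert a nanomolar IC50 to pIC50 = -log10(IC50 in mol/L).

    1 nM -> 9.0; 1000 nM (1 uM) -> 6.0. Strictly decreasing in IC50.
    """
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: pIC50 -> IC50 in nM."""
    return 10.0 ** (9.0 - pic50)


def _parse_number(text: str) -> float:
    s = text.strip()
    for ch in _MINUS_VARIANTS:
        s = s.replace(ch, "-")
    return float(s)


def read_compound_table(path, schema: DescriptorSchema | None = None) -> Dataset:
    """Read a CSV compound table into a Dataset.

    Required column: ``id``. Recognized optional columns: ``smiles``,
    ``IC50_nM`` (or ``ic50_nM``), ``pIC50``, ``split``; every other column is
    treated as a descriptor. Unicode minus signs are normalized. Rows missing
    a modeling descriptor are retained but flagged incomplete/unassigned.
    """
    schema = schema or DescriptorSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if "id" not in cols:
        raise CompoundTableError(f"{path}: compound table must have an 'id' column")
    special = {"id", "smiles", "split"}
    ic50_col = next((c for c in cols if c.lower() == "ic50_nm"), None)
    pic50_col = next((c for c in cols if c.lower() == "pic50"), None)
    special |= {c for c in (ic50_col, pic50_col) if c}
    descriptor_cols = [c for c in cols if c not in special]

    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        desc: dict[str, float] = {}
        for c in descriptor_cols:
            cell = str(row[c]).strip()
            if cell == "":
                continue
            try:
                desc[c] = _parse_number(cell)
            except ValueError as exc:
                raise CompoundTableError(
                    f"{path}: non-numeric value {cell!r} in row {i + 1}, "
                    f"column {c!r}"
                ) from exc
        kwargs: dict = {}
        if ic50_col and str(row[ic50_col]).strip():
            kwargs["ic50_nM"] = _parse_number(str(row[ic50_col]))
        if pic50_col and str(row[pic50_col]).strip():
            kwargs["pic50"] = _parse_number(str(row[pic50_col]))
        smiles = str(row["smiles"]).strip() if "smiles" in cols else ""
        split = str(row["split"]).strip() if "split" in cols else ""
        rec = CompoundRecord(
            id=str(row["id"]).strip(),
            descriptors=desc,
            smiles=smiles or None,
            split=split or "unassigned",
            **kwargs,
        )
        if not rec.has_descriptors(MODELING_DESCRIPTORS):
            rec.complete = False
            rec.split = "unassigned"
        records.append(rec)
    return Dataset(records, schema=schema)


def write_compound_table(ds: Dataset, path) -> None:
    """Write a Dataset back to CSV at full float precision (round-trips)."""
    names = [n for n in ds.schema.names
             if any(n in r.descriptors for r in ds.records)]
    extra = sorted({n for r in ds.records for n in r.descriptors} - set(names))
    names += extra
    with open(path, "w", encoding="utf-8", newline="") as fh:
        header = ["id", "smiles"] + names + ["pIC50", "split"]
        fh.write(",".join(header) + "\n")
        for r in ds.records:
            cells = [r.id, r.smiles or ""]
            cells += [repr(r.descriptors[n]) if n in r.descriptors else ""
                      for n in names]
            cells.append(repr(r.pic50) if r.pic50 is not None else "")
            cells.append(r.split)
            fh.write(",".join(cells) + "\n")


def random_split(ds: Dataset, fractions: dict[str, float], seed: int) -> Dataset:
    """Assign split labels by a seeded shuffle.

    Each non-train split receives round(fraction * n) records; the remainder
    goes to train (deterministic tie-break). The same seed always yields the
    same assignment, and the per-label counts do not depend on input order.
    """
    n = len(ds.records)
    if n == 0:
        raise CompoundTableError("cannot split an empty dataset")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {total}")
    unknown = set(fractions) - set(SPLIT_LABELS)
    if unknown:
        raise ValueError(f"unknown split labels {sorted(unknown)}")

    counts = {label: int(round(frac * n)) for label, frac in fractions.items()
              if label != "train"}
    n_other = sum(counts.values())
    if n_other > n:
        # rounding overshoot on tiny n: trim the largest split
        biggest = max(counts, key=counts.get)
        counts[biggest] -= n_other - n
        n_other = n
    counts["train"] = n - n_other if "train" in fractions else 0
    if "train" not in fractions and n_other < n:
        # no train fraction requested: leftovers stay unassigned
        counts["unassigned"] = n - n_other

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    pos = 0
    for label in ("train", "test", "validation", "unassigned"):
        c = counts.get(label, 0)
        labels[order[pos:pos + c]] = label
        pos += c
    out = [replace(r, split=labels[i]) for i, r in enumerate(ds.records)]
    return Dataset(out, schema=ds.schema, seed=seed)


def as_xy(data, names=MODELING_DESCRIPTORS, split: str | None = None):
    """Coerce a Dataset (optionally one split) or an (X, y) pair to arrays."""
    if isinstance(data, Dataset):
        ds = data.subset(split) if split else data
        return ds.descriptor_matrix(names), ds.response()
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)
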