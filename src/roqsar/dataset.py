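"""Packaged study data and dataset assembly/IO.

The 72-compound fixture (names, SMILES, experimental and model-predicted
rejection percentages, train/test/validation labels) ships inside the
package as a CSV plus a YAML metadata file carrying the study constants
and an integrity checksum.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .exceptions import AssemblyError, FixtureError

logger = logging.getLogger(__name__)

SPLITS = ("training", "test", "validation")

#: canonical dataset CSV columns (descriptors sit between compound and these)
RESERVED_COLUMNS = ("compound", "response", "split", "censored")


@dataclass(frozen=True)
class CompoundRecord:
    id: int
    name: str
    abbrev: str
    smiles: str
    rejection_exp: float
    rejection_exp_censored: bool
    rejection_ann_paper: float
    split: str

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if not 0.0 <= self.rejection_exp <= 100.0:
            raise ValueError(f"rejection out of range: {self.rejection_exp}")


@dataclass
class QsarDataset:
    """Aligned compounds x descriptors matrix with response and split labels."""

    X: pd.DataFrame
    y: pd.Series
    splits: pd.Series
    censored: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.splits)):
            raise AssemblyError("X, y and split labels must have equal length")
        if self.X.isna().any().any() or self.y.isna().any():
            raise AssemblyError("dataset contains missing cells")
        if self.censored is None:
            self.censored = pd.Series(False, index=self.X.index)

    @property
    def n_compounds(self) -> int:
        return len(self.X)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, split: str) -> "QsarDataset":
        mask = self.splits == split
        return QsarDataset(self.X[mask], self.y[mask], self.splits[mask],
                           self.censored[mask], dict(self.meta))

    def split_counts(self) -> dict[str, int]:
        return {s: int((self.splits == s).sum()) for s in SPLITS}


def _data_text(filename: str) -> str:
    return (resources.files("roqsar.data") / filename).read_text()


def study_metadata() -> dict:
    return yaml.safe_load(_data_text("metadata.yaml"))


def study_constants() -> dict:
    return study_metadata()["study_constants"]


def load_fixture() -> list[CompoundRecord]:
    """Load the packaged 72-compound table, verifying its checksum."""
    meta = study_metadata()["fixture"]
    raw = _data_text("compounds.csv")
    digest = hashlib.sha256(raw.encode()).hexdigest()
    if digest != meta["sha256"]:
        raise FixtureError(
            f"fixture checksum mismatch: {digest} != {meta['sha256']}"
        )
    frame = pd.read_csv((resources.files("roqsar.data") / "compounds.csv").open("r"))
    records = [
        CompoundRecord(
            id=int(row.id), name=row.name_, abbrev=row.abbrev, smiles=row.smiles,
            rejection_exp=float(row.rejection_exp),
            rejection_exp_censored=bool(row.censored),
            rejection_ann_paper=float(row.rejection_ann),
            split=row.split,
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    if len(records) != meta["n_compounds"]:
        raise FixtureError(f"expected {meta['n_compounds']} records, got {len(records)}")
    counts = {s: sum(1 for r in records if r.split == s) for s in SPLITS}
    if counts != meta["split_counts"]:
        raise FixtureError(f"split counts {counts} disagree with metadata")
    return records


def assemble(records: list[CompoundRecord], descriptor_table: pd.DataFrame,
             response: str = "experimental") -> QsarDataset:
    """Align fixture records with a descriptor table into a QsarDataset.

    ``response`` selects the experimental rejection column or the paper's
    model-predicted column; censored experimental values enter as their
    numeric surrogate (logged).
    """
    if response not in ("experimental", "ann_paper"):
        raise ValueError(f"unknown response {response!r}")
    names = [r.name for r in records]
    missing = sorted(set(names) - set(descriptor_table.index))
    if missing:
        raise AssemblyError(f"descriptor table missing compounds: {missing}")
    n_censored = sum(r.rejection_exp_censored for r in records)
    if n_censored and response == "experimental":
        logger.info("using numeric surrogate for %d censored rejection value(s)",
                    n_censored)
    X = descriptor_table.loc[names].copy()
    X.index.name = None
    values = [r.rejection_exp if response == "experimental" else r.rejection_ann_paper
              for r in records]
    y = pd.Series(values, index=X.index, name="response")
    splits = pd.Series([r.split for r in records], index=X.index, name="split")
    censored = pd.Series([r.rejection_exp_censored for r in records],
                         index=X.index, name="censored")
    return QsarDataset(X, y, splits, censored, meta=dict(study_constants()))


def write_csv(dataset: QsarDataset, path) -> None:
    """Persist a dataset as CSV at full precision (lossless round trip)."""
    frame = dataset.X.copy()
    frame.insert(0, "compound", frame.index)
    frame["response"] = dataset.y.values
    frame["split"] = dataset.splits.values
    frame["censored"] = dataset.censored.astype(int).values
    frame.to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> QsarDataset:
    """Read a dataset CSV written by :func:`write_csv`.

    Unknown extra columns are preserved untouched in ``meta['extra']``.
    """
    frame = pd.read_csv(path)
    if "compound" not in frame.columns:
        raise AssemblyError(f"{path}: malformed header, 'compound' column missing")
    if "response" not in frame.columns:
        raise AssemblyError(f"{path}: 'response' column missing")
    frame = frame.set_index("compound")
    frame.index.name = None
    if "split" not in frame.columns:
        frame["split"] = "training"
    censored = (frame["censored"].astype(bool) if "censored" in frame.columns
                else pd.Series(False, index=frame.index))
    known = {"response", "split", "censored"}
    descriptor_cols = [c for c in frame.columns
                       if c not in known and pd.api.types.is_numeric_dtype(frame[c])]
    extra_cols = [c for c in frame.columns if c not in known and c not in descriptor_cols]
    meta: dict = {}
    if extra_cols:
        meta["extra"] = frame[extra_cols].copy()
    return QsarDataset(frame[descriptor_cols].astype(float),
                       frame["response"].astype(float),
                       frame["split"].copy(), censored, meta=meta)


def export_fixture(outdir) -> None:
    """Write the packaged fixture CSV and metadata YAML to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "compounds.csv").write_text(_data_text("compounds.csv"))
    (out / "metadata.yaml").write_text(_data_text("metadata.yaml"))
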