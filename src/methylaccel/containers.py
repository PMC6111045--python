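"""Shared data containers and their text-file dialects.

The on-disk conventions follow the wide layout common to methylation-array
exports: probes as rows and samples as columns for beta / detection-p /
beadcount matrices; in memory everything is samples x probes, which is the
natural orientation for per-sample prediction and regression.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

#: The seven blood cell types used for intrinsic/extrinsic acceleration.
CELL_TYPES = (
    "naive CD8+ T",
    "exhausted CD8+ T",
    "plasmablast",
    "CD4+ T",
    "NK",
    "monocyte",
    "granulocyte",
)

#: The three age-varying immune measures entering the extrinsic (EEAA) combination.
EEAA_CELL_TYPES = ("naive CD8+ T", "exhausted CD8+ T", "plasmablast")


class MethylAccelError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass
class BetaMatrix:
    """Methylation beta values with companion QC matrices.

    Parameters
    ----------
    beta : DataFrame
        Samples x probes methylation fractions in [0, 1].
    detection_p : DataFrame
        Same shape/labels; per-measurement detection p-values.
    beadcount : DataFrame, optional
        Same shape/labels; non-negative integer bead counts. May be absent,
        in which case beadcount-based QC rules are skipped.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    beadcount: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.beta.empty:
            raise MethylAccelError("beta matrix is empty")
        vals = self.beta.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise MethylAccelError("beta values must lie in [0, 1]")
        for name, other in (("detection_p", self.detection_p), ("beadcount", self.beadcount)):
            if other is None:
                continue
            if other.shape != self.beta.shape:
                raise MethylAccelError(f"{name} shape {other.shape} != beta shape {self.beta.shape}")
            if not (other.index.equals(self.beta.index) and other.columns.equals(self.beta.columns)):
                raise MethylAccelError(f"{name} labels do not match beta labels")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def subset(self, samples=None, probes=None) -> "BetaMatrix":
        """Return a new BetaMatrix restricted to the given samples/probes."""
        samples = self.sample_ids if samples is None else pd.Index(samples)
        probes = self.probe_ids if probes is None else pd.Index(probes)
        return BetaMatrix(
            beta=self.beta.loc[samples, probes],
            detection_p=self.detection_p.loc[samples, probes],
            beadcount=None if self.beadcount is None else self.beadcount.loc[samples, probes],
        )

    # -- wide text IO (probes as rows, samples as columns) -------------------

    @staticmethod
    def _read_wide(path: Union[str, Path], sep: str) -> pd.DataFrame:
        df = pd.read_csv(path, sep=sep, index_col=0)
        return df.T  # probes-as-rows on disk -> samples x probes in memory

    @classmethod
    def read(cls, beta_path, detp_path, beadcount_path=None, sep: str = ",") -> "BetaMatrix":
        beta = cls._read_wide(beta_path, sep)
        detp = cls._read_wide(detp_path, sep)
        bead = None if beadcount_path is None else cls._read_wide(beadcount_path, sep).astype(int)
        return cls(beta=beta, detection_p=detp, beadcount=bead)

    def write(self, beta_path, detp_path, beadcount_path=None, sep: str = ",",
              float_format: str = "%.10g") -> None:
        self.beta.T.to_csv(beta_path, sep=sep, float_format=float_format)
        self.detection_p.T.to_csv(detp_path, sep=sep, float_format=float_format)
        if beadcount_path is not None and self.beadcount is not None:
            self.beadcount.T.to_csv(beadcount_path, sep=sep)


@dataclass
class ClockModel:
    """A linear epigenetic clock: transformed age = intercept + sum(w_j * beta_j).

    ``transform`` is either ``"identity"`` or ``"log_linear"`` (the standard
    age calibration that is logarithmic below ``adult_age`` and linear above).
    """

    name: str
    intercept: float
    weights: pd.Series  # index: probe ids, values: coefficients
    transform: str = "identity"
    adult_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log_linear"):
            raise MethylAccelError(f"unknown transform {self.transform!r}")
        if self.transform == "log_linear":
            if self.adult_age is None or self.adult_age <= 0:
                raise MethylAccelError("log_linear transform requires adult_age > 0")
        if not np.all(np.isfinite(self.weights.to_numpy(dtype=float))):
            raise MethylAccelError("clock weights must be finite")

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "ClockModel":
        """Read a clock coefficient CSV.

        Metadata lines start with ``#`` (``# name=...``, ``# intercept=...``,
        ``# transform=...``, ``# adult_age=...``); the body has columns
        ``probe_id,weight``.
        """
        meta = {}
        body = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            elif line.strip():
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)))
        adult_age = meta.get("adult_age")
        return cls(
            name=meta.get("name", Path(path).stem),
            intercept=float(meta["intercept"]),
            weights=pd.Series(df["weight"].to_numpy(), index=df["probe_id"]),
            transform=meta.get("transform", "identity"),
            adult_age=None if adult_age in (None, "", "none") else float(adult_age),
        )

    def write_csv(self, path: Union[str, Path]) -> None:
        lines = [f"# name={self.name}", f"# intercept={self.intercept!r}",
                 f"# transform={self.transform}"]
        if self.adult_age is not None:
            lines.append(f"# adult_age={self.adult_age!r}")
        lines.append("probe_id,weight")
        lines += [f"{p},{w!r}" for p, w in self.weights.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CellReference:
    """Reference beta profiles for the seven blood cell types.

    ``reference_betas`` is probes x cell types, betas in [0, 1]; the column
    roster is pinned to :data:`CELL_TYPES`.
    """

    reference_betas: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.reference_betas.columns) != CELL_TYPES:
            raise MethylAccelError(
                f"cell reference columns must be exactly {CELL_TYPES}, "
                f"got {tuple(self.reference_betas.columns)}"
            )
        vals = self.reference_betas.to_numpy()
        if vals.min() < 0 or vals.max() > 1:
            raise MethylAccelError("reference betas must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.reference_betas.index

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "CellReference":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.reference_betas.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class Pedigree:
    """A pedigree table: one row per individual, parents precede offspring.

    Columns: ``individual_id``, ``sire_id``, ``dam_id`` (None/NaN for unknown),
    ``sex`` ("male"/"female").
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("individual_id", "sire_id", "dam_id", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise MethylAccelError(f"pedigree missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        t = self.table
        ids = t["individual_id"]
        if ids.duplicated().any():
            raise MethylAccelError("duplicate individual ids in pedigree")
        pos = {i: k for k, i in enumerate(ids)}
        sex = dict(zip(ids, t["sex"]))
        for _, row in t.iterrows():
            for parent, want in (("sire_id", "male"), ("dam_id", "female")):
                p = row[parent]
                if pd.isna(p) or p is None:
                    continue
                if p not in pos:
                    raise MethylAccelError(f"parent {p!r} of {row['individual_id']!r} not in pedigree")
                if pos[p] >= pos[row["individual_id"]]:
                    raise MethylAccelError(
                        f"parent {p!r} does not precede offspring {row['individual_id']!r}")
                if sex[p] != want:
                    raise MethylAccelError(f"{parent[:-3]} {p!r} is not {want}")

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.table["individual_id"])

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["0", "NA"])
        df.columns = list(cls.REQUIRED)
        return cls(df)

    def write_tsv(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out["sire_id"] = out["sire_id"].fillna("NA")
        out["dam_id"] = out["dam_id"].fillna("NA")
        out.to_csv(path, sep="\t", index=False)
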