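"""In-memory containers shared by every pipeline stage.

The central object is :class:`OmicsMatrix`, a features-in-rows,
samples-in-columns real matrix tagged with the molecular layer it carries
(mRNA, miRNA, methylation beta values, protein abundance, or a cell-by-gene
single-cell matrix stored cell-in-columns).  Missing values are encoded as
NaN, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("mrna", "mirna", "methylation", "protein", "cell")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed, with location information."""


@dataclass
class OmicsMatrix:
    """Features x samples continuous matrix for one molecular layer.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
        mRNA/miRNA/protein values are log2-scale abundances; methylation
        values are beta values in [0, 1].
    layer
        One of ``mrna``, ``mirna``, ``methylation``, ``protein``, ``cell``.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("matrix values must be numeric")
        if self.layer == "methylation":
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValidationError(
                    "methylation beta values must lie in [0, 1]; "
                    f"observed range [{finite.min():g}, {finite.max():g}]"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.data.loc[:, list(sample_ids)], self.layer)


RESPONSE_LEVELS = ("R", "NR", "NA")


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints, ICB response labels and covariates.

    ``data`` is indexed by unique sample id.  Recognised columns:
    ``os_time``/``os_event`` (days, 0/1), ``pfs_time``/``pfs_event``,
    ``response`` (R / NR / NA); everything else is treated as a covariate.
    """

    data: pd.DataFrame

    SURVIVAL_COLS = ("os_time", "os_event", "pfs_time", "pfs_event")

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        for col in ("os_event", "pfs_event"):
            if col in self.data.columns:
                vals = self.data[col].dropna().unique()
                bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
                if bad:
                    raise ValidationError(
                        f"{col} must be 0/1; found {bad[:5]}"
                    )
        for col in ("os_time", "pfs_time"):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if (vals < 0).any():
                    raise ValidationError(f"{col} contains negative times")
        if "response" in self.data.columns:
            vals = self.data["response"].fillna("NA").unique()
            bad = [v for v in vals if v not in RESPONSE_LEVELS]
            if bad:
                raise ValidationError(
                    f"response labels must be R/NR/NA; found {bad[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def covariate_columns(self) -> list[str]:
        reserved = set(self.SURVIVAL_COLS) | {"response"}
        return [c for c in self.data.columns if c not in reserved]

    def survival(self, endpoint: str = "OS") -> tuple[pd.Series, pd.Series]:
        """Return (time, event) for the requested endpoint, rows with data."""
        endpoint = endpoint.upper()
        if endpoint not in ("OS", "PFS"):
            raise ValueError(f"endpoint must be OS or PFS, got {endpoint!r}")
        tcol, ecol = (
            ("os_time", "os_event") if endpoint == "OS" else ("pfs_time", "pfs_event")
        )
        if tcol not in self.data.columns or ecol not in self.data.columns:
            raise ValidationError(f"clinical table lacks {tcol}/{ecol}")
        sub = self.data[[tcol, ecol]].dropna()
        return sub[tcol].astype(float), sub[ecol].astype(int)


class GeneSetCollection:
    """Ordered named collection of non-empty gene-id sets."""

    def __init__(self, sets: dict[str, list[str]] | None = None):
        self._sets: dict[str, list[str]] = {}
        if sets:
            for name, genes in sets.items():
                self.add(name, genes)

    def add(self, name: str, genes) -> None:
        if name in self._sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        # de-duplicate, preserving first-seen order
        seen: dict[str, None] = {}
        for g in genes:
            g = str(g).strip()
            if g:
                seen.setdefault(g, None)
        members = list(seen)
        if not members:
            raise ValidationError(f"gene set {name!r} is empty")
        self._sets[name] = members

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __iter__(self):
        return iter(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def items(self):
        return ((k, list(v)) for k, v in self._sets.items())


@dataclass
class FerroptosisSignature:
    """The FPS model definition: disjoint pro- and anti-ferroptosis gene sets.

    Roles come from the curated annotation (ferroptosis driver vs suppressor),
    never from the direction of the outcome association.
    """

    pro_genes: tuple[str, ...]
    anti_genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pro_genes = tuple(dict.fromkeys(self.pro_genes))
        self.anti_genes = tuple(dict.fromkeys(self.anti_genes))
        if not self.pro_genes or not self.anti_genes:
            raise ValidationError("signature needs at least one pro and one anti gene")
        overlap = set(self.pro_genes) & set(self.anti_genes)
        if overlap:
            raise ValidationError(f"pro/anti sets overlap: {sorted(overlap)[:5]}")

    @property
    def size(self) -> int:
        return len(self.pro_genes) + len(self.anti_genes)

    def swapped(self) -> "FerroptosisSignature":
        return FerroptosisSignature(self.anti_genes, self.pro_genes, self.provenance)
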