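"""Amino-acid z-scale construction and lookup.

A z-scale is a low-dimensional principal-property encoding of the 20
natural amino acids: each residue is mapped to a small number of scores
(here three: z1 ~ size/shape, z2 ~ polarity/lipophilicity, z3 ~ charge)
obtained by PCA of a table of physicochemical properties.  The published
three-component scale ships as packaged reference data; :func:`build_scale`
reconstructs a scale of the same kind from any residues-by-properties
table by centered, unit-variance PCA.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: Property names used to orient component signs, in component order:
#: z1 follows molecular volume, z2 the octanol/water logP, z3 net charge.
SIGN_ANCHORS = ("volume", "QPlogPo/w", "Tot Q")


class ZScaleError(ValueError):
    """Raised for invalid property tables or unknown residues."""


@dataclass(frozen=True)
class PropertyTable:
    """Residues-by-properties matrix feeding scale construction.

    Parameters
    ----------
    residues
        One-letter residue codes (unique, order preserved).
    property_names
        Labels of the physicochemical descriptors (unique).
    values
        Matrix of shape ``(len(residues), len(property_names))``; every
        entry must be finite.  Units may be heterogeneous (volumes,
        masses, counts, logP units, areas, charges) — autoscaling inside
        :func:`build_scale` removes them.
    """

    residues: tuple[str, ...]
    property_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "property_names", tuple(self.property_names))
        if len(set(self.residues)) != len(self.residues):
            raise ZScaleError("duplicate residue codes in property table")
        if len(set(self.property_names)) != len(self.property_names):
            raise ZScaleError("duplicate property names in property table")
        if vals.shape != (len(self.residues), len(self.property_names)):
            raise ZScaleError(
                f"values shape {vals.shape} does not match "
                f"{len(self.residues)} residues x {len(self.property_names)} properties"
            )
        if not np.all(np.isfinite(vals)):
            raise ZScaleError("property table contains non-finite entries")
        if len(self.residues) < 2 or len(self.property_names) < 2:
            raise ZScaleError("need at least 2 residues and 2 properties for PCA")

    @classmethod
    def from_csv(cls, path) -> "PropertyTable":
        """Read a table whose first column holds residue codes."""
        df = pd.read_csv(path)
        residues = tuple(str(r).strip().upper() for r in df.iloc[:, 0])
        return cls(residues, tuple(df.columns[1:]), df.iloc[:, 1:].to_numpy(float))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.property_names))
        df.insert(0, "residue", list(self.residues))
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class AminoAcidScale:
    """Per-residue principal-property scores.

    ``scores`` maps a one-letter residue code to its component tuple
    (z1, z2, z3 for the packaged scale).  ``loadings`` (properties x
    components) and ``explained_variance`` (fractions, non-increasing)
    are present when the scale was built from a :class:`PropertyTable`
    and ``None`` for the packaged published scale.
    """

    scores: dict[str, tuple[float, ...]]
    loadings: np.ndarray | None = None
    property_names: tuple[str, ...] | None = None
    explained_variance: np.ndarray | None = None
    _upper: dict[str, tuple[float, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_upper", {k.upper(): tuple(v) for k, v in self.scores.items()}
        )

    @property
    def n_components(self) -> int:
        return len(next(iter(self.scores.values())))

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self._upper

    def lookup(self, residue: str) -> tuple[float, ...]:
        """Return the score tuple for ``residue`` (case-insensitive)."""
        key = residue.upper()
        if key not in self._upper:
            raise ZScaleError(
                f"residue {residue!r} is not in the scale alphabet "
                f"({''.join(sorted(self._upper))})"
            )
        return self._upper[key]

    def as_frame(self) -> pd.DataFrame:
        cols = [f"z{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame.from_dict(self.scores, orient="index", columns=cols)

    def to_csv(self, path) -> None:
        df = self.as_frame()
        df.insert(0, "residue", df.index)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AminoAcidScale":
        df = pd.read_csv(path)
        scores = {
            str(row.iloc[0]).strip().upper(): tuple(float(v) for v in row.iloc[1:])
            for _, row in df.iterrows()
        }
        return cls(scores=scores)


def load_published_scale() -> AminoAcidScale:
    """Load the packaged three-component z-scale for the 20 residues."""
    ref = importlib.resources.files("cppqsar.data") / "zscale.csv"
    with importlib.resources.as_file(ref) as path:
        scale = AminoAcidScale.from_csv(path)
    if set(scale.scores) != set(STANDARD_RESIDUES):
        raise ZScaleError("packaged scale does not cover the 20-residue alphabet")
    return scale


def autoscale(values: np.ndarray) -> np.ndarray:
    """Center each column to mean 0 and scale to unit (sample) variance."""
    vals = np.asarray(values, dtype=float)
    std = vals.std(axis=0, ddof=1)
    if np.any(std == 0):
        return (vals - vals.mean(axis=0)) / np.where(std == 0, 1.0, std)
    return (vals - vals.mean(axis=0)) / std


def build_scale(props: PropertyTable, n_components: int = 3) -> AminoAcidScale:
    """Construct a z-scale from a property table by autoscaled PCA.

    Each property column is mean-centered and scaled to unit variance,
    the correlation structure is eigendecomposed, and residue scores are
    the projections onto the leading unit-norm eigenvectors.  Component
    signs are oriented so the loading of the anchor property (molecular
    volume for z1, logP for z2, net charge for z3) is positive; when the
    anchor is absent the largest-magnitude loading is made positive.

    Raises
    ------
    ZScaleError
        If a property column has zero variance or ``n_components``
        exceeds ``min(n_residues - 1, n_properties)``.
    """
    n_res, n_props = props.values.shape
    max_comp = min(n_res - 1, n_props)
    if not 1 <= n_components <= max_comp:
        raise ZScaleError(
            f"n_components={n_components} out of range 1..{max_comp} "
            f"for a {n_res} x {n_props} table"
        )
    std = props.values.std(axis=0, ddof=1)
    if np.all(std == 0):
        # every row identical: centering leaves nothing, all scores vanish
        zeros = np.zeros(n_components)
        return AminoAcidScale(
            scores={r: tuple(zeros) for r in props.residues},
            loadings=np.zeros((n_props, n_components)),
            property_names=props.property_names,
            explained_variance=zeros.copy(),
        )
    zero = np.flatnonzero(std == 0)
    if zero.size:
        names = ", ".join(props.property_names[i] for i in zero)
        raise ZScaleError(f"zero-variance property column(s): {names}")

    X = autoscale(props.values)
    # correlation matrix eigendecomposition == SVD of autoscaled X; deterministic
    corr = (X.T @ X) / (n_res - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    loadings = eigvecs[:, :n_components].copy()
    lower_names = [p.lower() for p in props.property_names]
    for j in range(n_components):
        anchor = SIGN_ANCHORS[j] if j < len(SIGN_ANCHORS) else None
        if anchor is not None and anchor.lower() in lower_names:
            pivot = lower_names.index(anchor.lower())
        else:
            pivot = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1.0

    scores = X @ loadings
    explained = eigvals[:n_components] / eigvals.sum()
    return AminoAcidScale(
        scores={r: tuple(scores[i]) for i, r in enumerate(props.residues)},
        loadings=loadings,
        property_names=props.property_names,
        explained_variance=explained,
    )


def lookup_z(scale: AminoAcidScale, residue: str) -> tuple[float, ...]:
    """Return the stored score tuple for a one-letter residue code."""
    return scale.lookup(residue)
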