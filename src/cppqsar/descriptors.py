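"""Global peptide descriptors on the amino-acid z-scale.

A peptide is encoded residue-by-residue as z-score triples, and a fixed
set of whole-sequence descriptors is derived for QSAR modeling: mean
z-scores, z-scale helical moments (the Eisenberg hydrophobic-moment
construction with the hydrophilicity scale replaced by each z-component),
absolute N-/C-terminal mean differences, side-chain steric bulk, net
hydrogen-bond donation, charge counts and the hydrophilic-residue ratio.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .zscale import AminoAcidScale, STANDARD_RESIDUES, ZScaleError

#: Residues carrying +1 at physiological pH (His counted as charged).
POSITIVE_RESIDUES = frozenset("RKH")
#: Residues carrying -1 at physiological pH.
NEGATIVE_RESIDUES = frozenset("DE")

#: Hydrophilic residue set for the hydrophilic-ratio descriptor.  This is
#: the minimal standard set consistent with all published reference
#: ratios; note His and Thr are deliberately excluded (see docs/methods.md).
HYDROPHILIC_SET = frozenset("RKDENQS")

#: Phase angle between consecutive residues of an ideal alpha helix, degrees.
ALPHA_HELIX_DELTA = 100.0


def _load_sidechain_tables() -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    ref = importlib.resources.files("cppqsar.data") / "sidechain.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    heavy = dict(zip(df["residue"], df["heavy_atoms"].astype(int)))
    donors = dict(zip(df["residue"], df["hbond_donors"].astype(int)))
    acceptors = dict(zip(df["residue"], df["hbond_acceptors"].astype(int)))
    return heavy, donors, acceptors


SIDECHAIN_HEAVY_ATOMS, SIDECHAIN_HBOND_DONORS, SIDECHAIN_HBOND_ACCEPTORS = (
    _load_sidechain_tables()
)


@dataclass(frozen=True)
class Peptide:
    """A labeled sequence over the 20-residue one-letter alphabet.

    The sequence is upper-cased and validated at construction; termini
    are treated as capped (acetyl/amide), so they contribute no charge.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        for pos, ch in enumerate(seq):
            if ch not in STANDARD_RESIDUES:
                raise ValueError(
                    f"peptide {self.id!r}: unknown residue {ch!r} at position "
                    f"{pos + 1} (alphabet {STANDARD_RESIDUES})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def encode(peptide: Peptide, scale: AminoAcidScale) -> np.ndarray:
    """Encode a peptide as an (N, k) array of per-residue z-scores."""
    try:
        return np.array([scale.lookup(ch) for ch in peptide.sequence], dtype=float)
    except ZScaleError as exc:  # scale narrower than the 20-residue alphabet
        for pos, ch in enumerate(peptide.sequence):
            if ch not in scale:
                raise ZScaleError(
                    f"peptide {peptide.id!r}: residue {ch!r} at position "
                    f"{pos + 1} is not in the scale"
                ) from exc
        raise


def mean_z(peptide: Peptide, scale: AminoAcidScale) -> np.ndarray:
    """Component-wise arithmetic mean of the encoded sequence."""
    return encode(peptide, scale).mean(axis=0)


def z_moment(
    peptide: Peptide,
    scale: AminoAcidScale,
    component: int,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> float:
    """Helical moment of one z-component at phase angle ``delta_deg``.

    mu = sqrt((sum_n H_n sin(n*delta))^2 + (sum_n H_n cos(n*delta))^2),
    n = 1..N, where H_n is the selected z-score of residue n and delta is
    the per-residue phase (100 degrees for an ideal alpha helix).  The
    result is the modulus of the sequence's descriptor vector sum on the
    helical wheel, hence non-negative and invariant to the index origin.
    """
    if component not in (1, 2, 3):
        raise ValueError(f"component must be 1, 2 or 3, got {component}")
    H = encode(peptide, scale)[:, component - 1]
    angles = np.deg2rad(delta_deg) * np.arange(1, len(H) + 1)
    return float(np.hypot((H * np.sin(angles)).sum(), (H * np.cos(angles)).sum()))


def _terminal_fragments(peptide: Peptide, mode: str) -> tuple[Peptide, Peptide]:
    # local import: datasets imports Peptide from here
    from .datasets import truncate

    if mode == "halves":
        if len(peptide) < 2:
            warnings.warn(
                f"peptide {peptide.id!r} too short to halve; terminal "
                "difference uses the whole sequence for both fragments",
                stacklevel=3,
            )
            return peptide, peptide
        return truncate(peptide, "n_half"), truncate(peptide, "c_half")
    if mode in ("first_last_5", "first_last_10"):
        k = 5 if mode == "first_last_5" else 10
        if len(peptide) < k:
            warnings.warn(
                f"peptide {peptide.id!r} shorter than {k} residues; terminal "
                f"difference ({mode}) uses the whole sequence for both fragments",
                stacklevel=3,
            )
            return peptide, peptide
        return truncate(peptide, f"first_{k}"), truncate(peptide, f"last_{k}")
    raise ValueError(f"unknown terminal-difference mode {mode!r}")


def terminal_difference(
    peptide: Peptide, scale: AminoAcidScale, mode: str = "halves"
) -> np.ndarray:
    """|mean_z(N-terminal fragment) - mean_z(C-terminal fragment)|.

    ``mode`` is one of ``halves`` (N-half vs C-half, N-half longer for odd
    lengths), ``first_last_5`` or ``first_last_10``.  Sequences shorter
    than the fixed cut use the whole sequence for both fragments (zero
    difference, with a warning).
    """
    nt, ct = _terminal_fragments(peptide, mode)
    return np.abs(mean_z(nt, scale) - mean_z(ct, scale))


def charge_descriptors(peptide: Peptide) -> dict[str, float]:
    """Residue charge counts and derived charge descriptors.

    Positives are {R, K, H} at +1 each, negatives {D, E} at -1; capped
    termini contribute nothing.  The positive/negative ratio is NaN
    (flagged undefined) when there are no negative residues.
    """
    seq = peptide.sequence
    counts = {
        "n_arg": seq.count("R"),
        "n_his": seq.count("H"),
        "n_lys": seq.count("K"),
        "n_asp": seq.count("D"),
        "n_glu": seq.count("E"),
    }
    n_pos = counts["n_arg"] + counts["n_lys"] + counts["n_his"]
    n_neg = counts["n_asp"] + counts["n_glu"]
    total = n_pos - n_neg
    ratio = math.nan if n_neg == 0 else n_pos / n_neg
    return {
        **counts,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "total_charge": total,
        "mean_net_charge": total / len(seq),
        "positive_negative_ratio": ratio,
    }


def hydrophilic_ratio(
    peptide: Peptide, hydrophilic_set: frozenset[str] = HYDROPHILIC_SET
) -> int:
    """Percent of residues in the hydrophilic set, rounded half-up."""
    frac = 100 * sum(ch in hydrophilic_set for ch in peptide.sequence) / len(peptide)
    return int(math.floor(frac + 0.5))


def steric_bulk(peptide: Peptide) -> float:
    """Mean number of non-hydrogen atoms in the side chains."""
    return sum(SIDECHAIN_HEAVY_ATOMS[ch] for ch in peptide.sequence) / len(peptide)


def net_hbond_donation(peptide: Peptide) -> float:
    """Mean (side-chain H-bond donors - acceptors) per residue."""
    net = sum(
        SIDECHAIN_HBOND_DONORS[ch] - SIDECHAIN_HBOND_ACCEPTORS[ch]
        for ch in peptide.sequence
    )
    return net / len(peptide)


@dataclass(frozen=True)
class DescriptorVector:
    """Fixed-order global descriptor set for one peptide.

    Field order is the stable feature order used for modeling; see
    :meth:`feature_names` / :meth:`as_features`.
    """

    mean_z1: float
    mean_z2: float
    mean_z3: float
    moment_z1: float
    moment_z2: float
    moment_z3: float
    diff_half_z1: float
    diff_half_z2: float
    diff_half_z3: float
    diff_5_z1: float
    diff_5_z2: float
    diff_5_z3: float
    diff_10_z1: float
    diff_10_z2: float
    diff_10_z3: float
    steric_bulk: float
    net_hbond_donation: float
    total_charge: int
    mean_net_charge: float
    n_arg: int
    n_his: int
    n_lys: int
    n_asp: int
    n_glu: int
    n_positive: int
    n_negative: int
    positive_negative_ratio: float
    hydrophilic_ratio: int

    @classmethod
    def feature_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_features(self) -> np.ndarray:
        """Numeric feature vector in field order.

        The undefined (NaN-flagged) positive/negative ratio is mapped to
        ``n_positive`` — i.e. the denominator is clamped to one — so the
        model matrix stays finite.
        """
        vals = [getattr(self, name) for name in self.feature_names()]
        idx = self.feature_names().index("positive_negative_ratio")
        if math.isnan(vals[idx]):
            vals[idx] = float(self.n_positive)
        return np.array(vals, dtype=float)


def descriptor_vector(
    peptide: Peptide,
    scale: AminoAcidScale,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> DescriptorVector:
    """Compute the full fixed-order descriptor vector for one peptide."""
    mz = mean_z(peptide, scale)
    charges = charge_descriptors(peptide)
    return DescriptorVector(
        mean_z1=mz[0],
        mean_z2=mz[1],
        mean_z3=mz[2],
        moment_z1=z_moment(peptide, scale, 1, delta_deg),
        moment_z2=z_moment(peptide, scale, 2, delta_deg),
        moment_z3=z_moment(peptide, scale, 3, delta_deg),
        **dict(
            zip(
                [f"diff_half_z{i}" for i in (1, 2, 3)],
                terminal_difference(peptide, scale, "halves"),
            )
        ),
        **dict(
            zip(
                [f"diff_5_z{i}" for i in (1, 2, 3)],
                terminal_difference(peptide, scale, "first_last_5"),
            )
        ),
        **dict(
            zip(
                [f"diff_10_z{i}" for i in (1, 2, 3)],
                terminal_difference(peptide, scale, "first_last_10"),
            )
        ),
        steric_bulk=steric_bulk(peptide),
        net_hbond_donation=net_hbond_donation(peptide),
        **charges,
        hydrophilic_ratio=hydrophilic_ratio(peptide),
    )


def descriptor_table(
    peptides: list[Peptide],
    scale: AminoAcidScale,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> pd.DataFrame:
    """Descriptor matrix for a peptide list, one row per peptide.

    Rows are indexed by peptide id; columns follow the stable
    :class:`DescriptorVector` field order.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-sequence terminal warnings
        rows = [
            descriptor_vector(p, scale, delta_deg).as_features() for p in peptides
        ]
    return pd.DataFrame(
        rows,
        index=pd.Index([p.id for p in peptides], name="id"),
        columns=DescriptorVector.feature_names(),
    )
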