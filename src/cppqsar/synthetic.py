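"""Synthetic labeled peptide corpora and property tables.

Real CPP corpora are compiled from external databases; this module
generates stand-ins with the statistical structure the modeling pipeline
assumes, so every stage is testable offline.  Positives are drawn with
elevated Arg/Lys frequency (cationicity is the dominant CPP signature)
and, optionally, with apolar residues placed at helical spacing so the
z-scale moment descriptor responds (amphipathicity).  Negatives are
compositionally near-uniform random peptides.  A second generator emits
low-rank-plus-noise amino-acid property tables with known latent scores,
for PCA recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .datasets import LabeledPeptideSet
from .descriptors import Peptide
from .zscale import PropertyTable, STANDARD_RESIDUES

#: Apolar residues used for helical-face placement when amphipathic.
APOLAR_FACE = "LIFW"

#: Composition-gap presets: target Arg/Lys mass in positives.
SEPARATION_PRESETS = {"weak": 0.20, "moderate": 0.32, "strong": 0.45}
#: Background Arg/Lys mass (2 of 20 residues) used for negatives.
UNIFORM_CATIONIC_FRACTION = 0.10
#: CPP-like shaping of the positive class (applied only when a
#: composition gap is requested): anionic residues are nearly absent in
#: known CPPs, and His — itself cationic — stays at background frequency
#: rather than being diluted by the Arg/Lys boost.
CPP_ANION_MASS = 0.01
CPP_HIS_MASS = 1.0 / 20


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus generator settings.

    ``separation`` maps to a cationic-fraction preset for the positive
    class unless ``cationic_fraction_pos`` is given explicitly; negatives
    default to the uniform-composition background (0.10).  Positive and
    negative classes draw from disjoint random streams spawned from
    ``seed``, so changing one class's settings never perturbs the other.
    """

    n_per_class: int = 450
    length_range: tuple[int, int] = (5, 30)
    separation: str = "strong"
    cationic_fraction_pos: float | None = None
    cationic_fraction_neg: float = UNIFORM_CATIONIC_FRACTION
    amphipathic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be at least 2")
        lo, hi = self.length_range
        if lo < 5 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}; min >= 5")
        if self.separation not in SEPARATION_PRESETS:
            raise ValueError(
                f"separation must be one of {sorted(SEPARATION_PRESETS)}"
            )
        for frac in (self.cationic_fraction_pos, self.cationic_fraction_neg):
            if frac is not None and not 0 <= frac <= 1:
                raise ValueError(f"cationic fraction {frac} outside [0, 1]")

    @property
    def pos_fraction(self) -> float:
        if self.cationic_fraction_pos is not None:
            return self.cationic_fraction_pos
        return SEPARATION_PRESETS[self.separation]


def _composition(cationic_fraction: float, cpp_like: bool = False) -> np.ndarray:
    """Residue probabilities with the given total mass on Arg+Lys.

    With ``cpp_like`` the distribution is additionally shaped like a
    cell-penetrating peptide: Asp+Glu share ``CPP_ANION_MASS`` in total
    and His keeps its background frequency; the remainder is spread
    uniformly over the other residues.
    """
    alphabet = STANDARD_RESIDUES
    probs = {"R": cationic_fraction / 2, "K": cationic_fraction / 2}
    if cpp_like:
        probs["D"] = probs["E"] = CPP_ANION_MASS / 2
        probs["H"] = CPP_HIS_MASS
    rest = 1.0 - sum(probs.values())
    others = [ch for ch in alphabet if ch not in probs]
    for ch in others:
        probs[ch] = rest / len(others)
    return np.array([probs[ch] for ch in alphabet])


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    amphipathic: bool,
) -> str:
    residues = list(rng.choice(list(STANDARD_RESIDUES), size=length, p=probs))
    if amphipathic:
        # one helical face: every ~3.6th position (i, i+3/i+4 spacing at
        # 100 deg/residue) gets an apolar residue, making the sequence's
        # polar/apolar moment large at the helical phase
        pos = 0
        while pos < length:
            residues[pos] = APOLAR_FACE[rng.integers(len(APOLAR_FACE))]
            pos += int(rng.integers(3, 5))
    return "".join(residues)


def generate_corpus(cfg: GeneratorConfig) -> LabeledPeptideSet:
    """Generate a deduplicated labeled corpus per the configuration.

    Exactly ``n_per_class`` unique sequences per class; positive and
    negative sequence sets are disjoint.  Deterministic under seed.
    """
    root = np.random.SeedSequence(cfg.seed)
    pos_stream, neg_stream = root.spawn(2)
    lo, hi = cfg.length_range
    # CPP-like shaping only when a composition gap is requested, so a
    # null configuration draws both classes from one distribution
    shaped = cfg.pos_fraction > cfg.cationic_fraction_neg
    sequences: set[str] = set()
    peptides, labels = [], []
    for label, stream, frac, cpp_like, amphipathic in (
        (1, pos_stream, cfg.pos_fraction, shaped, cfg.amphipathic),
        (0, neg_stream, cfg.cationic_fraction_neg, False, False),
    ):
        rng = np.random.default_rng(stream)
        probs = _composition(frac, cpp_like=cpp_like)
        made = 0
        while made < cfg.n_per_class:
            seq = _draw_sequence(
                rng, int(rng.integers(lo, hi + 1)), probs, amphipathic
            )
            if seq in sequences:
                continue
            sequences.add(seq)
            tag = "cpp" if label else "neg"
            peptides.append(Peptide(f"{tag}{made:05d}", seq))
            labels.append(label)
            made += 1
    return LabeledPeptideSet(
        tuple(peptides),
        tuple(labels),
        provenance=(
            f"synthetic corpus (separation={cfg.separation}, "
            f"pos_cationic={cfg.pos_fraction:.2f}, "
            f"neg_cationic={cfg.cationic_fraction_neg:.2f}, "
            f"amphipathic={cfg.amphipathic})"
        ),
        seed_log=({"operation": "generate_corpus", "seed": cfg.seed},),
    )


class SyntheticPropertyTable(NamedTuple):
    """A generated property table plus its generating latent structure."""

    table: PropertyTable
    scores: np.ndarray  # n_residues x latent_rank
    loadings: np.ndarray  # n_properties x latent_rank


def generate_property_table(
    n_residues: int = 20,
    n_properties: int = 12,
    latent_rank: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticPropertyTable:
    """Low-rank signal + i.i.d. Gaussian noise property table.

    The signal is an outer product of orthonormal latent residue scores
    and orthonormal property loadings with well-separated component
    strengths, so recovered component order and identity are stable; the
    generating scores are returned for parameter-recovery tests.
    """
    if latent_rank < 1 or latent_rank > min(n_residues, n_properties):
        raise ValueError(
            f"latent_rank={latent_rank} out of range for "
            f"{n_residues} x {n_properties}"
        )
    rng = np.random.default_rng(seed)
    strengths = 4.0 * 0.5 ** np.arange(latent_rank)
    scores = rng.standard_normal((n_residues, latent_rank))
    scores -= scores.mean(axis=0)
    scores, _ = np.linalg.qr(scores)  # orthonormal, still centered
    scores *= np.sqrt(n_residues)  # unit-variance scale per component
    loadings, _ = np.linalg.qr(rng.standard_normal((n_properties, latent_rank)))
    # equalize the signal variance each property receives, so that the
    # per-column autoscaling downstream is a uniform rescale and leaves
    # component identity intact: rotate pairs of loading rows (which
    # preserves column orthogonality) until row norms of L*diag(strength)
    # agree
    A = loadings * strengths
    for _ in range(200):
        norms = np.einsum("ij,ij->i", A, A)
        hi, lo = int(np.argmax(norms)), int(np.argmin(norms))
        if norms[hi] - norms[lo] < 1e-12:
            break
        dot = A[hi] @ A[lo]
        # angle equalizing the two row norms: tan(2 theta) = (nu-nv)/(2 u.v)
        theta = 0.5 * np.arctan2(norms[hi] - norms[lo], 2.0 * dot)
        c, s = np.cos(theta), np.sin(theta)
        A[[hi, lo]] = np.array([[c, -s], [s, c]]) @ A[[hi, lo]]
    values = scores @ A.T
    values += noise_sd * rng.standard_normal(values.shape)
    residues = (
        tuple(STANDARD_RESIDUES[:n_residues])
        if n_residues <= 20
        else tuple(f"r{i}" for i in range(n_residues))
    )
    table = PropertyTable(
        residues=residues,
        property_names=tuple(f"prop{i + 1}" for i in range(n_properties)),
        values=values,
    )
    return SyntheticPropertyTable(table, scores, loadings)
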