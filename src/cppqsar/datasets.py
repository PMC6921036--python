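"""Labeled peptide dataset assembly.

Covers the corpus bookkeeping around modeling: exact-sequence
deduplication (with removal of label-contradictory duplicates), class
balancing by seeded random deletion from the majority class, the six
terminal-truncation dataset variants (N-/C-half, first/last 5, first/last
10) and a seeded random train/test split.  Every random operation records
its seed in the set's ``seed_log`` so any derived dataset can be
regenerated from its manifest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .descriptors import Peptide

logger = logging.getLogger(__name__)

TRUNCATION_MODES = ("n_half", "c_half", "first_5", "last_5", "first_10", "last_10")


@dataclass(frozen=True)
class LabeledPeptideSet:
    """Peptides with parallel binary labels (1 = CPP, 0 = non-CPP)."""

    peptides: tuple[Peptide, ...]
    labels: tuple[int, ...]
    provenance: str = ""
    seed_log: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", tuple(self.peptides))
        object.__setattr__(self, "labels", tuple(int(l) for l in self.labels))
        object.__setattr__(self, "seed_log", tuple(self.seed_log))
        if len(self.peptides) != len(self.labels):
            raise ValueError("peptides and labels differ in length")
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(p.sequence for p in self.peptides)

    def class_counts(self) -> tuple[int, int]:
        """(n_negatives, n_positives)."""
        pos = sum(self.labels)
        return len(self) - pos, pos

    def subset(self, indices, provenance: str, extra_log: dict | None = None):
        log = self.seed_log + ((extra_log,) if extra_log else ())
        return LabeledPeptideSet(
            tuple(self.peptides[i] for i in indices),
            tuple(self.labels[i] for i in indices),
            provenance,
            log,
        )

    # ------------------------------------------------------------------ I/O
    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(p.sequence), id=p.id, description=f"label={l}")
            for p, l in zip(self.peptides, self.labels)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path, provenance: str = "") -> "LabeledPeptideSet":
        peptides, labels = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = 0
            for token in rec.description.split():
                if token.startswith("label="):
                    label = int(token.split("=", 1)[1])
            peptides.append(Peptide(rec.id, str(rec.seq)))
            labels.append(label)
        return cls(tuple(peptides), tuple(labels), provenance or str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"id": [p.id for p in self.peptides],
             "sequence": self.sequences,
             "label": self.labels}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "LabeledPeptideSet":
        df = pd.read_csv(path)
        ids = df["id"] if "id" in df else [f"pep{i}" for i in range(len(df))]
        return cls(
            tuple(Peptide(str(i), s) for i, s in zip(ids, df["sequence"])),
            tuple(int(l) for l in df["label"]),
            provenance or str(path),
        )

    def manifest(self) -> dict:
        neg, pos = self.class_counts()
        return {
            "n_total": len(self),
            "n_cpp": pos,
            "n_non_cpp": neg,
            "provenance": self.provenance,
            "seed_log": list(self.seed_log),
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)


def deduplicate(dataset: LabeledPeptideSet) -> LabeledPeptideSet:
    """Drop repeated sequences, keeping the first occurrence.

    Sequences are compared case-normalized (peptides are upper-cased at
    construction).  A sequence observed with both labels is contradictory
    evidence: every copy of it is removed and the conflict is logged.
    """
    first_label: dict[str, int] = {}
    conflicts: set[str] = set()
    for p, l in zip(dataset.peptides, dataset.labels):
        if p.sequence in first_label and first_label[p.sequence] != l:
            conflicts.add(p.sequence)
        first_label.setdefault(p.sequence, l)
    if conflicts:
        logger.warning(
            "removed %d sequence(s) with conflicting labels: %s",
            len(conflicts), ", ".join(sorted(conflicts)),
        )
    seen: set[str] = set()
    keep = []
    for i, p in enumerate(dataset.peptides):
        if p.sequence in conflicts or p.sequence in seen:
            continue
        seen.add(p.sequence)
        keep.append(i)
    return dataset.subset(
        keep,
        f"{dataset.provenance} | dedup (removed {len(dataset) - len(keep)}, "
        f"{len(conflicts)} label conflict(s))",
    )


def balance(dataset: LabeledPeptideSet, seed: int) -> LabeledPeptideSet:
    """Down-sample the majority class to the minority size.

    Deleted members are drawn uniformly at random (seeded) from the
    majority class only; the minority class is untouched.
    """
    labels = np.asarray(dataset.labels)
    n_neg, n_pos = dataset.class_counts()
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be non-empty to balance")
    if n_neg == n_pos:
        # nothing to delete, but the operation is still audit-logged
        return dataset.subset(
            range(len(dataset)),
            f"{dataset.provenance} | balanced (already balanced)",
            {"operation": "balance", "seed": seed, "n_deleted": 0},
        )
    majority = 0 if n_neg > n_pos else 1
    minority_size = min(n_neg, n_pos)
    maj_idx = np.flatnonzero(labels == majority)
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=minority_size, replace=False)
    keep = sorted(set(np.flatnonzero(labels != majority)) | set(keep_maj.tolist()))
    n_deleted = len(dataset) - len(keep)
    return dataset.subset(
        keep,
        f"{dataset.provenance} | balanced (deleted {n_deleted} from class {majority})",
        {"operation": "balance", "seed": seed, "n_deleted": n_deleted},
    )


def truncate(peptide: Peptide, mode: str) -> Peptide:
    """Terminal truncation of a single peptide.

    ``n_half`` keeps the first ceil(N/2) residues and ``c_half`` the last
    floor(N/2) (so the N-terminal half is the longer one for odd N, and
    n_half + c_half reconstructs the sequence).  ``first_k``/``last_k``
    keep the first/last min(k, N) residues.
    """
    seq = peptide.sequence
    n = len(seq)
    if mode == "n_half":
        out = seq[: math.ceil(n / 2)]
    elif mode == "c_half":
        out = seq[math.ceil(n / 2):]
    elif mode in ("first_5", "first_10"):
        out = seq[: int(mode.split("_")[1])]
    elif mode in ("last_5", "last_10"):
        out = seq[-int(mode.split("_")[1]):]
    else:
        raise ValueError(f"unknown truncation mode {mode!r}; one of {TRUNCATION_MODES}")
    if not out:
        raise ValueError(f"truncation {mode!r} of {peptide.id!r} (length {n}) is empty")
    return Peptide(peptide.id, out)


def make_truncation_datasets(
    dataset: LabeledPeptideSet,
) -> dict[str, LabeledPeptideSet]:
    """One dataset per truncation mode, labels and ids preserved."""
    out = {}
    for mode in TRUNCATION_MODES:
        out[mode] = replace(
            dataset,
            peptides=tuple(truncate(p, mode) for p in dataset.peptides),
            provenance=f"{dataset.provenance} | truncated:{mode}",
        )
    return out


def split(
    dataset: LabeledPeptideSet,
    fraction: float = 0.5,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[LabeledPeptideSet, LabeledPeptideSet]:
    """Seeded random partition into (train, test).

    ``fraction`` is the training share.  The default draw is simple
    random over the whole set; ``stratified=True`` samples the fraction
    within each class instead.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if stratified:
        train_idx: list[int] = []
        labels = np.asarray(dataset.labels)
        for cls in (0, 1):
            cls_idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(cls_idx)
            train_idx.extend(perm[: round(fraction * len(cls_idx))].tolist())
        train_idx = sorted(train_idx)
    else:
        perm = rng.permutation(n)
        train_idx = sorted(perm[: round(fraction * n)].tolist())
    test_idx = sorted(set(range(n)) - set(train_idx))
    if not train_idx or not test_idx:
        raise ValueError("split produced an empty side; adjust fraction or set size")
    log = {"operation": "split", "seed": seed, "fraction": fraction,
           "stratified": stratified}
    return (
        dataset.subset(train_idx, f"{dataset.provenance} | train", log),
        dataset.subset(test_idx, f"{dataset.provenance} | test", log),
    )
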