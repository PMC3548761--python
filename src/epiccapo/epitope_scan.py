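"""Proteome scanning for promiscuous-epitope candidates.

Viral protein sequences are cut into all length-9 windows, every window is
scored by each allele-specific model, and peptides predicted positive
(decision score > 0, or above an optional stricter threshold) for several
alleles across several strains are reported as promiscuous candidates.
"Shared across strains" means exact 9-mer identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classify import TrainedModel
from .encoding import CapoEncoder
from .residues import AA_TO_INDEX

logger = logging.getLogger(__name__)

WINDOW = 9


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    strain: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class ScanHit:
    peptide: str
    protein_id: str
    start: int  # 1-based offset of the window
    strain: str
    allele_name: str
    decision_score: float

    @property
    def positive(self) -> bool:
        return self.decision_score > 0


@dataclass(frozen=True)
class PromiscuousCandidate:
    peptide: str
    alleles: frozenset[str]
    strains: frozenset[str]

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def n_strains(self) -> int:
        return len(self.strains)


@dataclass
class AlleleContext:
    """Everything needed to score a peptide for one allele: the trained model,
    the encoder (potential subset + scaled PSM + contact map), and the mask of
    features kept by prefix selection (None = all)."""

    allele_name: str
    model: TrainedModel
    encoder: CapoEncoder
    feature_indices: np.ndarray | None = None

    def validate(self) -> None:
        missing = [name for name in ("model", "encoder") if getattr(self, name) is None]
        if missing:
            raise ConfigurationError(f"allele {self.allele_name!r}: missing {', '.join(missing)}")
        n = len(self.feature_indices) if self.feature_indices is not None else self.encoder.n_features
        if n != self.model.n_features:
            raise ConfigurationError(
                f"allele {self.allele_name!r}: model expects {self.model.n_features} features, "
                f"context supplies {n}"
            )

    def score_peptides(self, peptides: Sequence[str]) -> np.ndarray:
        X = self.encoder.encode_many(peptides)
        if self.feature_indices is not None:
            X = X[:, self.feature_indices]
        return self.model.decision_scores(X)


def sliding_nonamers(protein: ProteinRecord | str) -> list[tuple[str, int]]:
    """All 9-mer windows (peptide, 1-based start), in order.

    Windows containing a non-canonical letter (ambiguous or special residue)
    are skipped; the skip count is logged. Sequences shorter than 9 yield an
    empty list.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    windows: list[tuple[str, int]] = []
    skipped = 0
    for start in range(len(seq) - WINDOW + 1):
        pep = seq[start : start + WINDOW]
        if all(c in AA_TO_INDEX for c in pep):
            windows.append((pep, start + 1))
        else:
            skipped += 1
    if skipped:
        name = protein.id if isinstance(protein, ProteinRecord) else "<sequence>"
        logger.info("%s: skipped %d windows with non-canonical residues", name, skipped)
    return windows


def scan_proteome(
    proteins: Sequence[ProteinRecord], contexts: Sequence[AlleleContext]
) -> list[ScanHit]:
    """Score every window of every protein with every allele model.

    Each distinct peptide is scored once per allele and the score fanned out
    to all of its occurrences, so the hit count is windows x alleles.
    """
    for ctx in contexts:
        ctx.validate()
    occurrences: list[tuple[str, str, int, str]] = []  # peptide, protein_id, start, strain
    for prot in proteins:
        for pep, start in sliding_nonamers(prot):
            occurrences.append((pep, prot.id, start, prot.strain))
    unique_peps = sorted({o[0] for o in occurrences})
    hits: list[ScanHit] = []
    for ctx in contexts:
        if unique_peps:
            scores = dict(zip(unique_peps, ctx.score_peptides(unique_peps)))
        else:
            scores = {}
        for pep, protein_id, start, strain in occurrences:
            hits.append(
                ScanHit(
                    peptide=pep,
                    protein_id=protein_id,
                    start=start,
                    strain=strain,
                    allele_name=ctx.allele_name,
                    decision_score=float(scores[pep]),
                )
            )
    return hits


def promiscuous_candidates(
    hits: Iterable[ScanHit],
    min_alleles: int = 2,
    min_strains: int = 1,
    score_threshold: float = 0.0,
) -> list[PromiscuousCandidate]:
    """Aggregate hits by exact peptide identity and keep the promiscuous ones.

    A peptide is kept iff it is predicted positive (score > threshold) for at
    least ``min_alleles`` alleles and occurs in at least ``min_strains``
    strains. Output is sorted by (n_alleles desc, n_strains desc, peptide asc);
    the result is independent of the input hit order.
    """
    alleles_of: dict[str, set[str]] = {}
    strains_of: dict[str, set[str]] = {}
    for h in hits:
        strains_of.setdefault(h.peptide, set()).add(h.strain)
        if h.decision_score > score_threshold:
            alleles_of.setdefault(h.peptide, set()).add(h.allele_name)
    out = [
        PromiscuousCandidate(
            peptide=pep, alleles=frozenset(alleles_of.get(pep, ())), strains=frozenset(strains)
        )
        for pep, strains in strains_of.items()
    ]
    out = [c for c in out if c.n_alleles >= min_alleles and c.n_strains >= min_strains]
    out.sort(key=lambda c: (-c.n_alleles, -c.n_strains, c.peptide))
    return out


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_strain_fasta(path: str | Path, strain: str) -> list[ProteinRecord]:
    """Read one strain's proteome FASTA; every record gets the strain label."""
    return [
        ProteinRecord(id=rec.id, strain=strain, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_hits_tsv(hits: Sequence[ScanHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "peptide": h.peptide,
                "protein": h.protein_id,
                "start": h.start,
                "strain": h.strain,
                "allele": h.allele_name,
                "score": h.decision_score,
                "positive": h.positive,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def write_candidates_tsv(cands: Sequence[PromiscuousCandidate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "n_alleles": c.n_alleles,
                "n_strains": c.n_strains,
                "alleles": ",".join(sorted(c.alleles)),
                "strains": ",".join(sorted(c.strains)),
            }
            for c in cands
        ]
    ).to_csv(path, sep="\t", index=False)
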