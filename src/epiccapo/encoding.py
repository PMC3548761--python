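"""Nonapeptide encoders: the contact-potential score, one-hot and descriptor
schemes, PSM rescaling and IC50 labelling.

The core encoding turns a nonapeptide into a 9K-dimensional vector whose
(9(k-1)+i)-th element (1-based) is

    S_k,i = T_i(u_i) * [ sum_{j : (i,j) in contacts} E_k(u_i, v_j) ] / n_contacts(i)

i.e. the average pairwise contact potential of peptide residue u_i against
the HLA residues it touches, weighted by the rescaled position-specific
score T_i. Positional scores are negated before rescaling so that larger
means more favourable, and mapped into a range excluding zero (default
[1, 10]) so a zero score never wipes out the contact-potential term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .potentials_io import (
    ContactMap,
    ContactPotentialMatrix,
    DescriptorTable,
    HlaAllele,
    PeptideRecord,
    PositionalScoringMatrix,
    ValidationError,
)
from .residues import AA_TO_INDEX

M = 9  # peptide length; fixed throughout

BINDER = "binder"
NONBINDER = "nonbinder"
IC50_CUTOFF_NM = 500.0


@dataclass(frozen=True)
class EncodedVector:
    """A numeric peptide representation.

    ``scheme`` is one of ``capo`` (feature-major blocks of 9 positions per
    potential / descriptor dimension), ``descriptor`` (same layout) or
    ``binary`` (position-major one-hot, 20 slots per position).
    """

    values: np.ndarray
    k_count: int
    scheme: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        expected = 20 * M if self.scheme == "binary" else M * self.k_count
        if v.shape != (expected,):
            raise ValidationError(f"encoded vector: length {v.shape}, expected ({expected},)")
        if not np.all(np.isfinite(v)):
            raise ValidationError("encoded vector: non-finite entries")
        if self.scheme == "binary":
            if not np.all((v == 0) | (v == 1)) or v.sum() != M:
                raise ValidationError("binary encoding must be one-hot per position")

    def __len__(self) -> int:
        return len(self.values)


def scale_psm(
    psm: PositionalScoringMatrix, scale_range: tuple[float, float] = (1.0, 10.0)
) -> PositionalScoringMatrix:
    """Negate a raw PSM and rescale it affinely into ``scale_range``.

    The map is global over all 9x20 entries:
        T' = lo + (hi - lo) * (-T - min(-T)) / (max(-T) - min(-T))
    so the output attains both endpoints exactly and the ordering of any two
    entries is the reverse of their input ordering. The range must exclude
    zero, otherwise a zero positional weight would erase the potential term.
    """
    if psm.scaled:
        raise ValidationError("PSM is already scaled")
    lo, hi = scale_range
    if not lo < hi:
        raise ValidationError(f"invalid scale range {scale_range}")
    if lo <= 0.0 <= hi:
        raise ValidationError(f"scale range {scale_range} must exclude zero")
    neg = -psm.values
    vmin, vmax = neg.min(), neg.max()
    if vmax == vmin:
        raise ValidationError("constant PSM cannot be rescaled (max == min)")
    scaled = lo + (hi - lo) * (neg - vmin) / (vmax - vmin)
    # pin the endpoints exactly despite floating rounding
    scaled[neg == vmin] = lo
    scaled[neg == vmax] = hi
    return PositionalScoringMatrix(values=scaled, scaled=True, scale_range=(lo, hi))


def capo_score(
    peptide: PeptideRecord | str,
    i: int,
    aapp: ContactPotentialMatrix,
    psm: PositionalScoringMatrix,
    hla: HlaAllele,
    cm: ContactMap,
) -> float:
    """S_k,i for one peptide position (``i`` 1-based) and one potential."""
    if not psm.scaled:
        raise ValidationError("capo_score requires a scaled PSM")
    cm.validate_for(hla)
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    u_i = seq[i - 1]
    contacts = cm.contacts_of(i)
    total = sum(aapp.value(u_i, hla.sequence[j - 1]) for j in contacts)
    return psm.score(i, u_i) * total / len(contacts)


class CapoEncoder:
    """Precomputed lookup tables for encoding many peptides against one allele.

    For each potential k and peptide position i the average potential against
    the contacted HLA residues depends only on the peptide residue, so a
    (K, 9, 20) table reduces encoding to indexed lookups.
    """

    def __init__(
        self,
        aapps: Sequence[ContactPotentialMatrix],
        psm: PositionalScoringMatrix,
        hla: HlaAllele,
        cm: ContactMap,
    ) -> None:
        if not aapps:
            raise ValidationError("need at least one contact potential")
        if not psm.scaled:
            raise ValidationError("encoder requires a scaled PSM")
        cm.validate_for(hla)
        self.aapps = list(aapps)
        self.psm = psm
        self.hla = hla
        self.cm = cm
        K = len(self.aapps)
        self._mean_pot = np.empty((K, M, 20))
        for i in range(1, M + 1):
            hla_res = [AA_TO_INDEX[hla.sequence[j - 1]] for j in cm.contacts_of(i)]
            for k, aapp in enumerate(self.aapps):
                self._mean_pot[k, i - 1, :] = aapp.values[:, hla_res].mean(axis=1)

    @property
    def k_count(self) -> int:
        return len(self.aapps)

    @property
    def n_features(self) -> int:
        return M * self.k_count

    def feature_names(self) -> list[str]:
        return [f"{a.id}:p{i}" for a in self.aapps for i in range(1, M + 1)]

    def encode(self, peptide: PeptideRecord | str) -> EncodedVector:
        seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
        u = np.array([AA_TO_INDEX[c] for c in seq])
        pos = np.arange(M)
        t = self.psm.values[pos, u]  # T_i(u_i)
        values = (t[None, :] * self._mean_pot[:, pos, u]).ravel()  # k-major blocks of 9
        return EncodedVector(values=values, k_count=self.k_count, scheme="capo")

    def encode_many(self, peptides: Sequence[PeptideRecord | str]) -> np.ndarray:
        """(n, 9K) matrix, rows in input order."""
        return np.array([self.encode(p).values for p in peptides])


def encode_capo(
    peptide: PeptideRecord | str,
    aapps: Sequence[ContactPotentialMatrix],
    psm: PositionalScoringMatrix,
    hla: HlaAllele,
    cm: ContactMap,
) -> EncodedVector:
    """Encode one nonapeptide with K potentials into a 9K-vector."""
    return CapoEncoder(aapps, psm, hla, cm).encode(peptide)


def encode_binary(peptide: PeptideRecord | str) -> EncodedVector:
    """Position-major one-hot encoding: 20 slots per position, 180 features."""
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    if len(seq) != M:
        raise ValidationError(f"peptide {seq!r}: length {len(seq)}, expected 9")
    values = np.zeros(20 * M)
    for i, aa in enumerate(seq):
        values[20 * i + AA_TO_INDEX[aa]] = 1.0
    return EncodedVector(values=values, k_count=20, scheme="binary")


def encode_descriptor(peptide: PeptideRecord | str, table: DescriptorTable) -> EncodedVector:
    """Per-residue descriptor encoding, laid out like the capo scheme:
    element (9(k-1)+i) is descriptor dimension k of the residue at position i."""
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    u = np.array([AA_TO_INDEX[c] for c in seq])
    values = table.values[u, :].T.ravel()  # (d, 9) -> k-major
    return EncodedVector(values=values, k_count=table.dim, scheme="descriptor")


def label_from_ic50(ic50_nM: float, cutoff_nM: float = IC50_CUTOFF_NM) -> str:
    """Binder iff IC50 strictly below the cutoff (default 500 nM)."""
    if not (np.isfinite(ic50_nM) and ic50_nM > 0):
        raise ValidationError(f"IC50 must be finite and positive, got {ic50_nM}")
    if not (np.isfinite(cutoff_nM) and cutoff_nM > 0):
        raise ValidationError(f"cutoff must be finite and positive, got {cutoff_nM}")
    return BINDER if ic50_nM < cutoff_nM else NONBINDER


def labels_of(peptides: Sequence[PeptideRecord], cutoff_nM: float = IC50_CUTOFF_NM) -> np.ndarray:
    """Binary label vector (1 = binder); IC50 takes precedence over a stored label."""
    out = np.empty(len(peptides), dtype=int)
    for n, p in enumerate(peptides):
        if p.ic50_nM is not None:
            out[n] = 1 if label_from_ic50(p.ic50_nM, cutoff_nM) == BINDER else 0
        elif p.label is not None:
            out[n] = 1 if p.label == BINDER else 0
        else:
            raise ValidationError(f"peptide {p.sequence!r}: no IC50 and no label")
    return out
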