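"""Seeded generators for every input the pipeline consumes.

The generator emulates the shape of the real inputs — symmetric contact
potentials, an HLA protein, a contact map with at least one contact per
peptide position, an unscaled positional scoring matrix — and plants a
recoverable signal in the peptide labels: a latent score

    z = beta * (w . x_std) + eps,   eps ~ Normal(0, noise_sd)

where x_std is the standardised capo encoding of the peptide and w a sparse
unit-norm weight vector. IC50 values are assigned by log10(IC50) = a - z
with the offset a solved so that the fraction of binders (IC50 < 500 nM)
matches the requested binder fraction. With beta = 0 the labels are pure
noise and any downstream AUC sits at chance; with large beta the signal is
recoverable by the full pipeline. No real binding motif (anchor positions
etc.) is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import M, CapoEncoder, scale_psm
from .potentials_io import (
    ContactMap,
    ContactPotentialMatrix,
    HlaAllele,
    PeptideRecord,
    PositionalScoringMatrix,
    ValidationError,
    write_contact_map,
    write_fasta,
    write_peptide_table,
    write_potential_tsv,
    write_psm,
)
from .residues import ALPHABETICAL

IC50_CUTOFF_NM = 500.0

# fixed offsets fanning the global seed out to component streams, so each
# component can be regenerated independently and bit-identically
_SEED_TAGS = {"aapp": 11, "hla": 23, "contacts": 37, "psm": 53, "peptides": 71, "labels": 89}


def _component_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SEED_TAGS[component]])


@dataclass(frozen=True)
class SyntheticSystemSpec:
    seed: int = 0
    n_aapps: int = 5
    hla_length: int = 275
    contacts_per_position: tuple[int, int] = (3, 6)
    n_peptides: int = 1000
    binder_fraction: float = 0.5
    signal_strength: float = 5.0  # beta
    noise_sd: float = 0.1
    sparsity: int | None = None  # latent support size; default max(3, F // 5)

    def __post_init__(self) -> None:
        if min(self.n_aapps, self.hla_length, self.n_peptides) < 1:
            raise ValidationError("counts must be positive")
        if not 0 < self.binder_fraction < 1:
            raise ValidationError("binder_fraction must lie in (0, 1)")
        lo, hi = self.contacts_per_position
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad contact range {self.contacts_per_position}")
        if hi > self.hla_length:
            raise ValidationError("more contacts per position than HLA residues")
        if self.signal_strength < 0 or self.noise_sd <= 0:
            raise ValidationError("signal_strength must be >= 0 and noise_sd > 0")


@dataclass
class FixtureBundle:
    spec: SyntheticSystemSpec
    aapps: list[ContactPotentialMatrix]
    hla: HlaAllele
    cm: ContactMap
    psm: PositionalScoringMatrix  # unscaled
    peptides: list[PeptideRecord] = field(default_factory=list)
    truth: np.ndarray | None = None  # latent weight vector over 9K features

    def encoder(self) -> CapoEncoder:
        return CapoEncoder(self.aapps, scale_psm(self.psm), self.hla, self.cm)


def gen_system(spec: SyntheticSystemSpec) -> FixtureBundle:
    """Generate potentials, HLA, contact map and PSM; reproducible by seed."""
    rng = _component_rng(spec.seed, "aapp")
    aapps = []
    for k in range(spec.n_aapps):
        tri = rng.uniform(-2.0, 2.0, size=(20, 20))
        sym = np.tril(tri) + np.tril(tri, -1).T  # mirror the lower triangle
        aapps.append(ContactPotentialMatrix(id=f"SYN{k + 1:04d}", values=sym))

    rng = _component_rng(spec.seed, "hla")
    hla_seq = "".join(rng.choice(list(ALPHABETICAL), size=spec.hla_length))
    hla = HlaAllele(name="HLA-SYN*01:01", sequence=hla_seq)

    rng = _component_rng(spec.seed, "contacts")
    lo, hi = spec.contacts_per_position
    pairs = set()
    for i in range(1, M + 1):
        count = int(rng.integers(lo, hi + 1))
        for j in rng.choice(spec.hla_length, size=count, replace=False):
            pairs.add((i, int(j) + 1))
    cm = ContactMap(allele_name=hla.name, pairs=frozenset(pairs))

    rng = _component_rng(spec.seed, "psm")
    psm = PositionalScoringMatrix(values=rng.normal(0.0, 1.0, size=(M, 20)), scaled=False)

    return FixtureBundle(spec=spec, aapps=aapps, hla=hla, cm=cm, psm=psm)


def _assign_ic50(z: np.ndarray, binder_fraction: float) -> np.ndarray:
    """log10(IC50) = a - z with a chosen so P(IC50 < 500) ~ binder_fraction."""
    a = np.log10(IC50_CUTOFF_NM) + np.quantile(z, 1.0 - binder_fraction)
    return 10.0 ** (a - z)


def _labelled_peptides(
    bundle: FixtureBundle, spec: SyntheticSystemSpec, support: np.ndarray
) -> list[PeptideRecord]:
    rng = _component_rng(spec.seed, "peptides")
    seqs = ["".join(rng.choice(list(ALPHABETICAL), size=M)) for _ in range(spec.n_peptides)]
    enc = bundle.encoder()
    X = enc.encode_many(seqs)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    rng_l = _component_rng(spec.seed, "labels")
    w = np.zeros(enc.n_features)
    w[support] = rng_l.normal(size=len(support))
    norm = np.linalg.norm(w)
    if norm > 0:
        w /= norm
    eps = rng_l.normal(0.0, spec.noise_sd, size=spec.n_peptides)
    z = spec.signal_strength * (Xs @ w) + eps
    ic50 = _assign_ic50(z, spec.binder_fraction)
    bundle.truth = w
    return [PeptideRecord(sequence=s, ic50_nM=float(v)) for s, v in zip(seqs, ic50)]


def gen_labelled_peptides(bundle: FixtureBundle, spec: SyntheticSystemSpec | None = None) -> list[PeptideRecord]:
    """Peptides with IC50s carrying the planted signal through the true encoding."""
    spec = spec or bundle.spec
    F = M * spec.n_aapps
    size = spec.sparsity if spec.sparsity is not None else max(3, F // 5)
    rng = _component_rng(spec.seed, "labels")
    support = rng.choice(F, size=min(size, F), replace=False)
    peptides = _labelled_peptides(bundle, spec, support)
    bundle.peptides = peptides
    return peptides


def gen_block_signal_fixture(
    bundle: FixtureBundle, signal_block: int, spec: SyntheticSystemSpec | None = None
) -> list[PeptideRecord]:
    """Labelled peptides whose latent weights live only in one potential's
    9-feature block (``signal_block`` 1-based)."""
    spec = spec or bundle.spec
    if not 1 <= signal_block <= spec.n_aapps:
        raise ValidationError(f"signal_block {signal_block} outside 1..{spec.n_aapps}")
    support = np.arange(M * (signal_block - 1), M * signal_block)
    peptides = _labelled_peptides(bundle, spec, support)
    bundle.peptides = peptides
    return peptides


def write_fixture_dir(bundle: FixtureBundle, outdir: str | Path) -> None:
    """Write a complete fixture directory (FASTA + TSVs + manifest)."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for aapp in bundle.aapps:
        write_potential_tsv(aapp, outdir / f"{aapp.id}.potential.tsv")
    write_fasta([(bundle.hla.name, bundle.hla.sequence)], outdir / "hla.fasta")
    write_contact_map(bundle.cm, outdir / "contact_map.tsv")
    write_psm(bundle.psm, outdir / "psm.tsv")
    if bundle.peptides:
        write_peptide_table(bundle.peptides, outdir / "peptides.tsv")
    manifest = {
        "seed": bundle.spec.seed,
        "n_aapps": bundle.spec.n_aapps,
        "aapp_ids": [a.id for a in bundle.aapps],
        "hla": bundle.hla.name,
        "hla_length": bundle.hla.length,
        "n_peptides": len(bundle.peptides),
        "binder_fraction": bundle.spec.binder_fraction,
        "signal_strength": bundle.spec.signal_strength,
        "noise_sd": bundle.spec.noise_sd,
        "ic50_cutoff_nM": IC50_CUTOFF_NM,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
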