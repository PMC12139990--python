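"""Synthetic fixture generator with planted, recoverable structure.

The generator emulates the structure of a real screening setup — a
compound library with approval flags, a protein library with predicted
binding-site ligands and confidences, a drug–indication mapping, and
per-indication gold-standard target sets — without any external data.

Planting: each indication draws a private *seed fingerprint*. Its approved
drugs are independent noisy copies of the seed, and its ``theme_size``
theme proteins carry binding-site ligands that are noisy copies of the
same seed (the indication's gold standard is exactly its theme proteins).
Everything else is background noise. Noise is a symmetric per-bit flip
applied with probability ``noise_rate``: at rate 0 copies are identical;
at rate 0.5 a copy is uniform over all bit sets and carries no trace of
the seed. Background fingerprints default to density 0.5 so that the
rate-0.5 limit is an exact null — planted and background compounds become
statistically indistinguishable.

By default fingerprints are random bit sets and no chemistry is involved;
``smiles_mode`` instead assigns real SMILES from a small fragment
vocabulary so the RDKit fingerprinting path is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    BindingSitePrediction,
    Compound,
    Fingerprint,
    GoldStandardTargets,
    IndicationMapping,
    Protein,
    heavy_atom_count,
)
from .io import (
    write_binding_site_table,
    write_compound_library,
    write_gold_standards,
    write_indication_mapping,
    write_table,
)

# Small valid-SMILES vocabulary for smiles_mode (one scaffold per indication).
_SMILES_VOCAB = [
    "c1ccccc1O", "c1ccccc1N", "c1ccccc1C(=O)O", "c1ccc2ccccc2c1", "c1ccncc1",
    "C1CCCCC1N", "CC(=O)Nc1ccccc1", "OCC1OC(O)C(O)C(O)C1O", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "c1ccc(cc1)S(=O)(=O)N", "CCN(CC)CCNC(=O)c1ccccc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(=O)Oc1ccccc1C(=O)O", "NC(=O)c1ccncc1", "OC(=O)CCC(=O)O", "Clc1ccc(cc1)C(=O)O",
    "COc1ccc(CCN)cc1", "CC1=CC(=O)CC(C)(C)C1", "OCCOc1ccccc1", "N#Cc1ccccc1",
    "CC(N)Cc1ccccc1", "OC(=O)c1cccnc1", "CSCCC(N)C(=O)O", "NCCc1c[nH]c2ccccc12",
    "CC(C)(C)NCC(O)c1ccccc1",
]


@dataclass
class SyntheticConfig:
    n_compounds: int = 200
    n_proteins: int = 100
    n_indications: int = 5
    drugs_per_indication: int = 5
    predictions_per_protein: int = 2
    fingerprint_width: int = 256
    fingerprint_density: float = 0.5
    theme_size: int = 10
    noise_rate: float = 0.05
    confidence_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0
    smiles_mode: bool = False

    def validate(self) -> None:
        lo, hi = self.confidence_range
        checks = [
            (self.n_compounds >= 1, "n_compounds must be >= 1"),
            (self.n_proteins >= 1, "n_proteins must be >= 1"),
            (self.n_indications >= 1, "n_indications must be >= 1"),
            (self.drugs_per_indication >= 2, "drugs_per_indication must be >= 2"),
            (self.theme_size >= 1, "theme_size must be >= 1"),
            (self.predictions_per_protein >= 1, "predictions_per_protein must be >= 1"),
            (self.n_indications * self.drugs_per_indication <= self.n_compounds,
             "too few compounds for the requested indications"),
            (self.n_indications * self.theme_size <= self.n_proteins,
             "theme_size * n_indications exceeds n_proteins"),
            (0.0 <= self.noise_rate <= 1.0, "noise_rate must be in [0,1]"),
            (0.0 < self.fingerprint_density < 1.0, "fingerprint_density must be in (0,1)"),
            (0.0 <= lo <= hi <= 1.0, "confidence_range must satisfy 0 <= lo <= hi <= 1"),
            (self.fingerprint_width >= 8, "fingerprint_width must be >= 8"),
            (not self.smiles_mode or self.n_indications <= len(_SMILES_VOCAB),
             "smiles_mode supports at most as many indications as vocabulary entries"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)


@dataclass
class IndicationTruth:
    indication_id: str
    approved_ids: tuple[str, ...]
    theme_protein_ids: tuple[str, ...]
    seed_fingerprint: Fingerprint


@dataclass
class SyntheticData:
    config: SyntheticConfig
    compounds: list[Compound]
    proteins: list[Protein]
    mappings: list[IndicationMapping]
    gold_standards: list[GoldStandardTargets]
    truth: list[IndicationTruth]


def _to_fp(mask: np.ndarray, width: int) -> Fingerprint:
    return Fingerprint(frozenset(int(i) for i in np.flatnonzero(mask)), width)


def generate(config: SyntheticConfig) -> SyntheticData:
    """Deterministically generate a full fixture from ``config.seed``."""
    config.validate()
    if config.smiles_mode:
        return _generate_smiles(config)
    rng = np.random.default_rng(config.seed)
    w = config.fingerprint_width

    def random_mask() -> np.ndarray:
        return rng.random(w) < config.fingerprint_density

    def mutate(mask: np.ndarray) -> np.ndarray:
        return mask ^ (rng.random(w) < config.noise_rate)

    n_approved = config.n_indications * config.drugs_per_indication
    seeds = [random_mask() for _ in range(config.n_indications)]

    compounds: list[Compound] = []
    heavy = rng.integers(1, 41, size=config.n_compounds)
    for i in range(config.n_compounds):
        cid = f"CPD{i:04d}"
        if i < n_approved:
            ind = i // config.drugs_per_indication
            mask = mutate(seeds[ind])
            approved = True
        else:
            mask = random_mask()
            approved = False
        compounds.append(Compound(id=cid, name=f"compound-{i:04d}",
                                  fingerprint=_to_fp(mask, w), approved=approved,
                                  heavy_atoms=int(heavy[i])))

    n_theme = config.n_indications * config.theme_size
    proteins: list[Protein] = []
    for j in range(config.n_proteins):
        pid = f"PRT{j:04d}"
        prot = Protein(id=pid, name=f"protein-{j:04d}")
        themed = j < n_theme
        ind = j // config.theme_size if themed else -1
        for s in range(config.predictions_per_protein):
            mask = mutate(seeds[ind]) if themed else random_mask()
            conf = float(rng.uniform(*config.confidence_range))
            prot.predictions.append(BindingSitePrediction(
                protein_id=pid, site_id=f"S{s}", ligand_fingerprint=_to_fp(mask, w),
                confidence=conf))
        proteins.append(prot)

    return _assemble(config, compounds, proteins, seeds, w)


def _generate_smiles(config: SyntheticConfig) -> SyntheticData:
    rng = np.random.default_rng(config.seed)
    w = config.fingerprint_width
    vocab = list(_SMILES_VOCAB)
    seed_smiles = vocab[: config.n_indications]
    background = vocab  # background compounds draw from the whole vocabulary

    def fp_of(smiles: str) -> Fingerprint:
        fp = Fingerprint.from_smiles(smiles, w)
        assert fp is not None, smiles
        return fp

    n_approved = config.n_indications * config.drugs_per_indication
    compounds: list[Compound] = []
    for i in range(config.n_compounds):
        cid = f"CPD{i:04d}"
        if i < n_approved:
            ind = i // config.drugs_per_indication
            smiles = seed_smiles[ind]
            if rng.random() < config.noise_rate:
                smiles = background[int(rng.integers(len(background)))]
            approved = True
        else:
            smiles = background[int(rng.integers(len(background)))]
            approved = False
        compounds.append(Compound(id=cid, name=f"compound-{i:04d}", smiles=smiles,
                                  fingerprint=fp_of(smiles), approved=approved,
                                  heavy_atoms=heavy_atom_count(smiles)))

    n_theme = config.n_indications * config.theme_size
    proteins: list[Protein] = []
    for j in range(config.n_proteins):
        pid = f"PRT{j:04d}"
        prot = Protein(id=pid, name=f"protein-{j:04d}")
        themed = j < n_theme
        ind = j // config.theme_size if themed else -1
        for s in range(config.predictions_per_protein):
            smiles = seed_smiles[ind] if themed else background[int(rng.integers(len(background)))]
            conf = float(rng.uniform(*config.confidence_range))
            prot.predictions.append(BindingSitePrediction(
                protein_id=pid, site_id=f"S{s}", ligand_fingerprint=fp_of(smiles),
                confidence=conf))
        proteins.append(prot)

    seeds = [fp_of(s) for s in seed_smiles]
    return _assemble(config, compounds, proteins, seeds, w, seeds_are_fp=True)


def _assemble(config: SyntheticConfig, compounds, proteins, seeds, width,
              seeds_are_fp: bool = False) -> SyntheticData:
    mappings, gold, truth = [], [], []
    for k in range(config.n_indications):
        ind_id = f"IND{k:02d}"
        lo = k * config.drugs_per_indication
        drug_ids = tuple(compounds[i].id for i in range(lo, lo + config.drugs_per_indication))
        plo = k * config.theme_size
        theme_ids = tuple(proteins[j].id for j in range(plo, plo + config.theme_size))
        mappings.append(IndicationMapping(ind_id, f"indication-{k:02d}", frozenset(drug_ids)))
        gold.append(GoldStandardTargets(ind_id, frozenset(theme_ids)))
        seed_fp = seeds[k] if seeds_are_fp else _to_fp(seeds[k], width)
        truth.append(IndicationTruth(ind_id, drug_ids, theme_ids, seed_fp))
    return SyntheticData(config, compounds, proteins, mappings, gold, truth)


def write_fixture(data: SyntheticData, outdir,
                  header_comments: Optional[Sequence[str]] = None) -> dict[str, Path]:
    """Write the fixture in the pipeline's tabular formats.

    The ground-truth record is a separate file never read by any stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.tsv",
        "binding_sites": outdir / "binding_sites.tsv",
        "mapping": outdir / "mapping.tsv",
        "gold": outdir / "gold_standards.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_compound_library(data.compounds, paths["compounds"], header_comments)
    write_binding_site_table(data.proteins, paths["binding_sites"], header_comments)
    write_indication_mapping(data.mappings, paths["mapping"], header_comments)
    write_gold_standards(data.gold_standards, paths["gold"], header_comments)
    truth_df = pd.DataFrame([{
        "indication_id": t.indication_id,
        "approved_ids": ";".join(t.approved_ids),
        "theme_protein_ids": ";".join(t.theme_protein_ids),
        "seed_fingerprint": t.seed_fingerprint.to_sparse(),
    } for t in data.truth])
    write_table(truth_df, paths["truth"], header_comments)
    return paths


def ground_truth_report(truth: Sequence[IndicationTruth], matrix, lists: Mapping,
                        target_cutoff: int = 10,
                        similarity_cutoff: int = 10) -> dict:
    """Recovery of the planted structure by the pipeline's own outputs.

    ``theme_recovery``: fraction of planted theme proteins found in the
    pooled rank-≤``target_cutoff`` targets of the indication's approved
    drugs. ``mutual_top``: fraction of ordered co-indicated drug pairs
    (d, d') with d' inside d's top-``similarity_cutoff`` similarity ranks.
    """
    from .targets import pooled_prediction_targets

    per_ind = {}
    theme_fracs, mutual_fracs = [], []
    for t in truth:
        pooled = pooled_prediction_targets(list(t.approved_ids), matrix, target_cutoff)
        theme = set(t.theme_protein_ids)
        theme_frac = len(pooled & theme) / len(theme)
        pairs = hits = 0
        for d in t.approved_ids:
            for other in t.approved_ids:
                if other == d:
                    continue
                pairs += 1
                if lists[d].rank_of(other) <= similarity_cutoff:
                    hits += 1
        mutual_frac = hits / pairs if pairs else 0.0
        per_ind[t.indication_id] = {"theme_recovery": theme_frac, "mutual_top": mutual_frac}
        theme_fracs.append(theme_frac)
        mutual_fracs.append(mutual_frac)
    return {
        "theme_recovery": sum(theme_fracs) / len(theme_fracs),
        "mutual_top": sum(mutual_fracs) / len(mutual_fracs),
        "per_indication": per_ind,
    }
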