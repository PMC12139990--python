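"""Interaction scoring: fingerprint Dice similarity × binding-site confidence.

A compound–protein interaction score is a docking surrogate: the compound's
fingerprint is compared (Sorensen–Dice) against every template ligand
predicted for the protein's binding sites; the highest similarity is then
multiplied by the confidence of the site achieving it. Applied across a
protein library this yields the compound's proteome-wide interaction
signature.

Two scoring variants are exposed:

``max-dice`` (default)
    Select the prediction with the highest Dice similarity (ties broken by
    taking the highest confidence among tied predictions), then multiply by
    that prediction's confidence.
``max-product``
    Maximise dice × confidence jointly over predictions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .model import Compound, Fingerprint, Protein, SignatureMatrix

VARIANTS = ("max-dice", "max-product")


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Sorensen–Dice coefficient 2|a∩b| / (|a|+|b|); 0 when both sets empty."""
    if a.width != b.width:
        raise ValidationError(f"fingerprint width mismatch: {a.width} != {b.width}")
    denom = len(a.bits) + len(b.bits)
    if denom == 0:
        return 0.0
    return 2 * len(a.bits & b.bits) / denom


def bandock_score(fingerprint: Optional[Fingerprint], protein: Protein,
                  variant: str = "max-dice") -> float:
    """Score one compound–protein pair; 0 for no predictions or no fingerprint."""
    if variant not in VARIANTS:
        raise ValidationError(f"unknown scoring variant {variant!r}")
    if fingerprint is None or not protein.predictions:
        return 0.0
    if variant == "max-product":
        return max(dice_similarity(fingerprint, p.ligand_fingerprint) * p.confidence
                   for p in protein.predictions)
    best_dice = 0.0
    best_conf = 0.0
    for p in protein.predictions:
        d = dice_similarity(fingerprint, p.ligand_fingerprint)
        if d > best_dice or (d == best_dice and p.confidence > best_conf):
            best_dice, best_conf = d, p.confidence
    return best_dice * best_conf


def build_signature_matrix(compounds: Sequence[Compound], proteins: Sequence[Protein],
                           variant: str = "max-dice") -> SignatureMatrix:
    """Score every compound against every protein (vectorised per protein).

    Unscoreable compounds (no fingerprint) get all-zero rows; proteins with
    no binding-site predictions get all-zero columns. Row and column order
    follow the input library order.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown scoring variant {variant!r}")
    n, m = len(compounds), len(proteins)
    values = np.zeros((n, m))
    if n == 0 or m == 0:
        return SignatureMatrix(values, [c.id for c in compounds], [p.id for p in proteins])

    width = next((c.fingerprint.width for c in compounds if c.fingerprint is not None), None)
    if width is None:  # nothing scoreable
        return SignatureMatrix(values, [c.id for c in compounds], [p.id for p in proteins])

    cbits = np.zeros((n, width), dtype=np.int64)
    scoreable = np.zeros(n, dtype=bool)
    for i, c in enumerate(compounds):
        if c.fingerprint is not None:
            if c.fingerprint.width != width:
                raise ValidationError("mixed fingerprint widths in compound library")
            cbits[i, list(c.fingerprint.bits)] = 1
            scoreable[i] = True
    csize = cbits.sum(axis=1)

    for j, prot in enumerate(proteins):
        preds = prot.predictions
        if not preds:
            continue
        k = len(preds)
        lbits = np.zeros((k, width), dtype=np.int64)
        conf = np.empty(k)
        for t, p in enumerate(preds):
            if p.ligand_fingerprint.width != width:
                raise ValidationError("ligand fingerprint width differs from compound width")
            lbits[t, list(p.ligand_fingerprint.bits)] = 1
            conf[t] = p.confidence
        lsize = lbits.sum(axis=1)
        inter = cbits @ lbits.T                       # (n, k) intersection counts
        denom = csize[:, None] + lsize[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            dice = np.where(denom > 0, 2 * inter / denom, 0.0)
        if variant == "max-product":
            col = (dice * conf[None, :]).max(axis=1)
        else:
            best = dice.max(axis=1)
            # confidence of the best-Dice prediction; ties -> highest confidence
            tied_conf = np.where(dice == best[:, None], conf[None, :], -1.0).max(axis=1)
            col = best * tied_conf
        values[:, j] = np.where(scoreable, col, 0.0)

    return SignatureMatrix(values, [c.id for c in compounds], [p.id for p in proteins])
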