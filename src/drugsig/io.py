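"""Tab-delimited readers and writers for every pipeline artifact.

All tables are UTF-8 TSV with a header line. Lines starting with ``#`` are
metadata comments (stage name, config hash) and are skipped on read.
Ligand structures and compound structures may be given either as SMILES
(fingerprinted at load) or as a precomputed sparse fingerprint string
``i1;i2;...`` so that synthetic fixtures can bypass chemistry entirely.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .model import (
    Compound,
    BindingSitePrediction,
    Fingerprint,
    GoldStandardTargets,
    IndicationMapping,
    Protein,
    SignatureMatrix,
    heavy_atom_count,
)

log = logging.getLogger(__name__)

_TRUE = {"1", "true", "yes", "y"}


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _write_lines(path, header_comments: Optional[Sequence[str]]):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for c in header_comments or []:
        lines.append(f"# {c}\n")
    return path, lines


def write_table(df: pd.DataFrame, path, header_comments: Optional[Sequence[str]] = None,
                float_format: Optional[str] = None, index: bool = False,
                index_label: Optional[str] = None) -> None:
    path, lines = _write_lines(path, header_comments)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.writelines(lines)
        df.to_csv(fh, sep="\t", index=index, index_label=index_label,
                  float_format=float_format, lineterminator="\n")


def _parse_structure(text: str, width: int) -> tuple[Optional[str], Optional[Fingerprint]]:
    """Return (smiles, fingerprint) for a structure cell.

    Digit-and-semicolon strings are sparse fingerprints; anything else is
    treated as SMILES. A None fingerprint from SMILES means a parse failure.
    """
    text = text.strip()
    if text == "":
        return None, None
    from .model import _SPARSE_RE

    if _SPARSE_RE.match(text):
        return None, Fingerprint.from_sparse(text, width)
    return text, Fingerprint.from_smiles(text, width)


def read_compound_library(path, fingerprint_width: int = 2048) -> list[Compound]:
    """Load compounds, fingerprinting SMILES rows at the given hash width.

    Rows with unparseable structures are kept but flagged unscoreable so
    that library-wide ranks stay comparable. Duplicate ids are an error.
    """
    df = _read_table(path, ["id", "name", "approved"])
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate compound ids {dupes}")
    compounds: list[Compound] = []
    n_flagged = 0
    for _, row in df.iterrows():
        smiles_cell = row.get("smiles", "") or ""
        fp_cell = row.get("fingerprint", "") or ""
        smiles: Optional[str] = None
        fp: Optional[Fingerprint] = None
        flagged = False
        if fp_cell.strip():
            fp = Fingerprint.from_sparse(fp_cell, fingerprint_width)
            smiles = smiles_cell.strip() or None
        elif smiles_cell.strip():
            smiles, fp = _parse_structure(smiles_cell, fingerprint_width)
            if fp is None:
                flagged = True
                n_flagged += 1
                log.warning("compound %s: unparseable SMILES %r; flagged unscoreable",
                            row["id"], smiles_cell)
        heavy = None
        ha_cell = (row.get("heavy_atoms", "") or "").strip()
        if ha_cell:
            heavy = int(ha_cell)
        elif smiles is not None and not flagged:
            heavy = heavy_atom_count(smiles)
        compounds.append(Compound(
            id=row["id"], name=row["name"], smiles=smiles if not flagged else smiles_cell,
            fingerprint=fp, approved=row["approved"].strip().lower() in _TRUE,
            heavy_atoms=heavy, flagged=flagged,
        ))
    log.info("read %d compounds (%d kept scoreable, %d flagged)",
             len(compounds), len(compounds) - n_flagged, n_flagged)
    return compounds


def write_compound_library(compounds: Sequence[Compound], path,
                           header_comments: Optional[Sequence[str]] = None) -> None:
    df = pd.DataFrame({
        "id": [c.id for c in compounds],
        "name": [c.name for c in compounds],
        "smiles": [c.smiles or "" for c in compounds],
        "fingerprint": ["" if (c.fingerprint is None or c.smiles) else c.fingerprint.to_sparse()
                        for c in compounds],
        "approved": [int(c.approved) for c in compounds],
        "heavy_atoms": ["" if c.heavy_atoms is None else c.heavy_atoms for c in compounds],
    })
    write_table(df, path, header_comments)


def read_binding_site_table(path, fingerprint_width: int = 2048) -> list[Protein]:
    """Group binding-site predictions (template ligand + confidence) by protein."""
    df = _read_table(path, ["protein_id", "site_id", "ligand", "confidence"])
    if df.empty:
        log.warning("%s: empty binding-site table", path)
        return []
    proteins: "OrderedDict[str, Protein]" = OrderedDict()
    for idx, row in df.iterrows():
        try:
            conf = float(row["confidence"])
        except ValueError:
            raise ValidationError(
                f"{path} row {idx + 2}: confidence {row['confidence']!r} is not a number")
        if not (0.0 <= conf <= 1.0):
            raise ValidationError(
                f"{path} row {idx + 2}: confidence {conf} outside [0,1] "
                f"(protein {row['protein_id']}, site {row['site_id']})")
        _, fp = _parse_structure(row["ligand"], fingerprint_width)
        if fp is None:
            fp = Fingerprint(frozenset(), fingerprint_width)
            log.warning("protein %s site %s: unparseable ligand %r; empty fingerprint",
                        row["protein_id"], row["site_id"], row["ligand"])
        pid = row["protein_id"]
        prot = proteins.get(pid)
        if prot is None:
            prot = proteins[pid] = Protein(id=pid, name=row.get("protein_name", "") or "")
        prot.predictions.append(BindingSitePrediction(
            protein_id=pid, site_id=row["site_id"], ligand_fingerprint=fp, confidence=conf))
    return list(proteins.values())


def write_binding_site_table(proteins: Sequence[Protein], path,
                             header_comments: Optional[Sequence[str]] = None) -> None:
    rows = []
    for prot in proteins:
        for pred in prot.predictions:
            rows.append({
                "protein_id": prot.id, "protein_name": prot.name, "site_id": pred.site_id,
                "ligand": pred.ligand_fingerprint.to_sparse(),
                "confidence": f"{pred.confidence:.6f}",
            })
    cols = ["protein_id", "protein_name", "site_id", "ligand", "confidence"]
    write_table(pd.DataFrame(rows, columns=cols), path, header_comments)


def read_indication_mapping(path, compounds: Sequence[Compound]) -> list[IndicationMapping]:
    """Load (indication, compound) associations, deduplicated to set semantics.

    Associations naming compounds absent from the library are skipped with a
    warning rather than failing the run.
    """
    df = _read_table(path, ["indication_id", "indication_name", "compound_id"])
    known = {c.id for c in compounds}
    assoc: "OrderedDict[str, tuple[str, set[str]]]" = OrderedDict()
    for _, row in df.iterrows():
        cid = row["compound_id"]
        if cid not in known:
            log.warning("indication %s: compound %r not in library; association skipped",
                        row["indication_id"], cid)
            continue
        name, ids = assoc.setdefault(row["indication_id"], (row["indication_name"], set()))
        ids.add(cid)
    mappings = [IndicationMapping(ind, name, frozenset(ids))
                for ind, (name, ids) in assoc.items()]
    for m in mappings:
        if not m.benchmarkable:
            log.warning("indication %s has %d approved drug(s); not benchmarkable",
                        m.indication_id, m.n_approved)
    return mappings


def write_indication_mapping(mappings: Sequence[IndicationMapping], path,
                             header_comments: Optional[Sequence[str]] = None) -> None:
    rows = [{"indication_id": m.indication_id, "indication_name": m.indication_name,
             "compound_id": cid}
            for m in mappings for cid in sorted(m.approved_compound_ids)]
    cols = ["indication_id", "indication_name", "compound_id"]
    write_table(pd.DataFrame(rows, columns=cols), path, header_comments)


def read_gold_standards(path) -> list[GoldStandardTargets]:
    df = _read_table(path, ["source_label", "protein_id"])
    grouped: "OrderedDict[str, set[str]]" = OrderedDict()
    for _, row in df.iterrows():
        grouped.setdefault(row["source_label"], set()).add(row["protein_id"])
    return [GoldStandardTargets(label, frozenset(ids)) for label, ids in grouped.items()]


def write_gold_standards(gold: Sequence[GoldStandardTargets], path,
                         header_comments: Optional[Sequence[str]] = None) -> None:
    rows = [{"source_label": g.source_label, "protein_id": pid}
            for g in gold for pid in sorted(g.protein_ids)]
    write_table(pd.DataFrame(rows, columns=["source_label", "protein_id"]), path,
                header_comments)


def write_matrix(matrix: SignatureMatrix, path, precision: int = 6,
                 header_comments: Optional[Sequence[str]] = None) -> None:
    """Write a signature matrix as TSV with fixed decimal precision (default 6)."""
    df = pd.DataFrame(matrix.values, index=matrix.compound_ids, columns=matrix.protein_ids)
    write_table(df, path, header_comments, float_format=f"%.{precision}f",
                index=True, index_label="compound_id")


def read_matrix(path, expected_compounds: Optional[Sequence[str]] = None,
                expected_proteins: Optional[Sequence[str]] = None) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy(dtype=float) if df.shape[1] else np.zeros((len(df.index), 0))
    mat = SignatureMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])
    if expected_compounds is not None and list(expected_compounds) != mat.compound_ids:
        raise FormatError(f"{path}: compound labels do not match expectation")
    if expected_proteins is not None and list(expected_proteins) != mat.protein_ids:
        raise FormatError(f"{path}: protein labels do not match expectation")
    return mat


def write_similarity_lists(lists, path, header_comments: Optional[Sequence[str]] = None) -> None:
    rows = [{"query_id": sl.query_id, "hit_id": e.compound_id,
             "distance": f"{e.distance:.12f}", "rank": e.rank}
            for sl in lists for e in sl.entries]
    cols = ["query_id", "hit_id", "distance", "rank"]
    write_table(pd.DataFrame(rows, columns=cols), path, header_comments)


def read_similarity_lists(path) -> "OrderedDict[str, object]":
    from .similarity import SimilarityEntry, SimilarityList

    df = _read_table(path, ["query_id", "hit_id", "distance", "rank"])
    out: "OrderedDict[str, SimilarityList]" = OrderedDict()
    for query, grp in df.groupby("query_id", sort=False):
        entries = [SimilarityEntry(r["hit_id"], float(r["distance"]), int(r["rank"]))
                   for _, r in grp.iterrows()]
        entries.sort(key=lambda e: e.rank)
        out[str(query)] = SimilarityList(str(query), entries)
    return out
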