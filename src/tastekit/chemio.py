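"""Ingestion, standardization, deduplication and partitioning of compounds.

Compounds arrive as SMILES, InChI, SMARTS or peptide FASTA strings, one per
line, optionally labelled with one of the four taste classes (bitter, sweet,
umami, other).  Every structure is normalized to a canonical parent SMILES —
salts and solvates stripped, charges neutralized where possible — so that the
canonical SMILES acts as the identity key for deduplication and for the
train/test partition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: taste classes in the fixed reporting order used throughout the package
TASTE_CLASSES: tuple[str, ...] = ("bitter", "sweet", "other", "umami")

INPUT_FORMATS: tuple[str, ...] = ("smiles", "inchi", "smarts", "fasta", "name")

#: the 20 canonical one-letter amino-acid codes
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: issue flag marking a record that failed parsing/standardization entirely
FATAL_FLAG = "fatal:unparseable"


class InvalidInputError(ValueError):
    """Raised for empty or malformed textual input."""


@dataclass
class MoleculeRecord:
    """One curated compound.

    ``canonical_smiles`` is the standardized parent structure; it is the
    identity key used for deduplication and split disjointness.  ``issues``
    accumulates curation flags; a record whose issues contain
    :data:`FATAL_FLAG` has no valid structure.
    """

    id: str
    input_text: str
    input_format: str = "smiles"
    canonical_smiles: str = ""
    label: str | None = None
    issues: list[str] = field(default_factory=list)

    @property
    def is_fatal(self) -> bool:
        return FATAL_FLAG in self.issues


@dataclass
class DatasetSplit:
    train: list[MoleculeRecord]
    test: list[MoleculeRecord]
    per_class_train_quota: dict[str, int]


def detect_format(text: str) -> str:
    """Classify a raw input string as smiles / inchi / fasta / smarts / name.

    Detection order is deterministic: InChI prefix, then parseable SMILES,
    then a string over the amino-acid alphabet only (peptide FASTA), then
    parseable SMARTS, and finally a free-text name.
    """
    text = text.strip()
    if not text:
        raise InvalidInputError("empty input string")
    if text.startswith("InChI="):
        return "inchi"
    if Chem.MolFromSmiles(text) is not None:
        return "smiles"
    if set(text.upper()) <= AMINO_ACIDS:
        return "fasta"
    if Chem.MolFromSmarts(text) is not None:
        return "smarts"
    return "name"


def peptide_to_smiles(sequence: str) -> str:
    """SMILES of the linear L-peptide with free N/C termini.

    >>> peptide_to_smiles("G")
    'NCC(=O)O'
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise InvalidInputError("empty peptide sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise InvalidInputError(
            f"invalid residue(s) {sorted(bad)} in peptide sequence"
        )
    mol = Chem.MolFromSequence(sequence)
    if mol is None:  # pragma: no cover - alphabet already validated
        raise InvalidInputError(f"could not build peptide from {sequence!r}")
    return Chem.MolToSmiles(mol)


# -- standardization ---------------------------------------------------------

NameResolver = Callable[[str], str | None]


def _parse_input(record: MoleculeRecord,
                 name_resolver: NameResolver | None) -> Chem.Mol | None:
    """Parse a record's raw input into an (unsanitized-ok) RDKit mol."""
    text = record.input_text.strip()
    fmt = record.input_format
    if fmt == "smiles":
        return Chem.MolFromSmiles(text)
    if fmt == "inchi":
        return Chem.MolFromInchi(text)
    if fmt == "fasta":
        try:
            return Chem.MolFromSmiles(peptide_to_smiles(text))
        except InvalidInputError:
            return None
    if fmt == "smarts":
        mol = Chem.MolFromSmarts(text)
        if mol is not None:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                return None
        return mol
    if fmt == "name":
        if name_resolver is None:
            return None
        smi = name_resolver(text)
        return Chem.MolFromSmiles(smi) if smi else None
    raise InvalidInputError(f"unknown input format {fmt!r}")


def standardize(record: MoleculeRecord,
                name_resolver: NameResolver | None = None) -> MoleculeRecord:
    """Return a copy with the standardized parent structure.

    Protocol: structure cleanup (functional-group / charge normalization),
    largest-fragment parent extraction (salt and solvate stripping), and
    neutralization of residual charges.  Checker findings are appended to
    ``issues``; an unparseable input yields the fatal flag instead.

    Idempotent: re-standardizing a standardized record is a no-op.
    """
    issues = list(record.issues)
    if record.canonical_smiles:
        mol = Chem.MolFromSmiles(record.canonical_smiles)
    else:
        mol = _parse_input(record, name_resolver)
        if mol is None and record.input_format == "name" and name_resolver is None:
            issues.append("name-resolution-disabled")
    if mol is None:
        if FATAL_FLAG not in issues:
            issues.append(FATAL_FLAG)
        return replace(record, canonical_smiles="", issues=issues)

    try:
        clean = rdMolStandardize.Cleanup(mol)
        n_frags = len(Chem.GetMolFrags(clean))
        parent = rdMolStandardize.FragmentParent(clean)
        parent = rdMolStandardize.Uncharger().uncharge(parent)
        smi = Chem.MolToSmiles(parent)
    except Exception:
        if FATAL_FLAG not in issues:
            issues.append(FATAL_FLAG)
        return replace(record, canonical_smiles="", issues=issues)

    if n_frags > 1 and "salt-or-mixture-stripped" not in issues:
        issues.append("salt-or-mixture-stripped")
    if (Chem.GetFormalCharge(mol) != 0 and Chem.GetFormalCharge(parent) == 0
            and "charges-neutralized" not in issues):
        issues.append("charges-neutralized")
    return replace(record, canonical_smiles=smi, issues=issues)


def deduplicate(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """Collapse records sharing a canonical parent structure.

    Records carrying a fatal issue are dropped.  For a group of duplicates
    with a single (or no) label, the first record is kept; a structure seen
    with two or more conflicting taste labels is removed entirely, since a
    single-label classifier cannot be trained on it.
    """
    by_smiles: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.is_fatal or not rec.canonical_smiles:
            continue
        if rec.canonical_smiles not in by_smiles:
            order.append(rec.canonical_smiles)
        by_smiles.setdefault(rec.canonical_smiles, []).append(rec)

    kept: list[MoleculeRecord] = []
    for smi in order:
        group = by_smiles[smi]
        labels = {r.label for r in group if r.label is not None}
        if len(labels) > 1:
            continue  # cross-class ambiguity: remove all
        winner = next((r for r in group if r.label is not None), group[0])
        if len(group) > 1:
            winner = replace(
                winner, issues=winner.issues + [f"deduplicated:{len(group)}"]
            )
        kept.append(winner)
    return kept


def make_split(records: Sequence[MoleculeRecord],
               quota: dict[str, int],
               seed: int) -> DatasetSplit:
    """Per-class uniform random train subset; the remainder becomes the test set.

    ``quota`` maps each taste class to the number of training compounds to
    draw without replacement (capped at the class size is *not* silent: a
    quota exceeding the class size raises, naming the class).
    """
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        if rec.label is None:
            raise InvalidInputError(f"record {rec.id!r} has no taste label")
        by_class.setdefault(rec.label, []).append(i)

    rng = np.random.default_rng(seed)
    train_idx: set[int] = set()
    for cls, n in quota.items():
        members = by_class.get(cls, [])
        if n > len(members):
            raise ValueError(
                f"quota {n} exceeds class size {len(members)} for class {cls!r}"
            )
        chosen = rng.choice(len(members), size=n, replace=False)
        train_idx.update(members[j] for j in chosen)

    train = [records[i] for i in sorted(train_idx)]
    test = [records[i] for i in range(len(records)) if i not in train_idx]
    return DatasetSplit(train=train, test=test, per_class_train_quota=dict(quota))


# -- file I/O ----------------------------------------------------------------

def _read_fasta(path: Path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    header, chunks = None, []
    def flush():
        if header is not None:
            records.append(MoleculeRecord(
                id=header, input_text="".join(chunks), input_format="fasta"))
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header, chunks = line[1:].split()[0], []
        else:
            chunks.append(line)
    flush()
    return records


def read_compounds(path: str | Path, fmt: str | None = None) -> list[MoleculeRecord]:
    """Read compounds from plain text (one per line), CSV, or FASTA.

    CSV columns: ``id,input[,label]`` (header required).  ``fmt`` forces an
    input format instead of per-line auto-detection.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        return _read_fasta(path)

    records: list[MoleculeRecord] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                text = (row.get("input") or row.get("smiles") or "").strip()
                if not text:
                    continue
                label = (row.get("label") or "").strip().lower() or None
                records.append(MoleculeRecord(
                    id=(row.get("id") or f"cpd{i}").strip(),
                    input_text=text,
                    input_format=fmt or detect_format(text),
                    label=label))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            records.append(MoleculeRecord(
                id=f"cpd{i}", input_text=line,
                input_format=fmt or detect_format(line)))
    return records


def write_curated(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write the curated table ``id,canonical_smiles,label,issues`` as CSV."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "canonical_smiles", "label", "issues"])
        for rec in records:
            writer.writerow([rec.id, rec.canonical_smiles,
                             rec.label or "", ";".join(rec.issues)])
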