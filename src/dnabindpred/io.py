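"""Readers and writers for every on-disk representation the pipeline touches.

Sequences come in as FASTA or as a dataset manifest (id, deposition date,
binary target, primary sequence).  Evolutionary profiles are PSI-BLAST ASCII
PSSM files (one row per residue, 20 log-odds integers).  Structural profiles
are per-residue tables of 3-state secondary structure (H/E/C) and relative
solvent accessibility (RSA).  Encoded descriptors travel as TSV feature
matrices that round-trip losslessly.

All per-residue arrays are 0-based internally; file positions are 1-based as
printed.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical amino-acid alphabet (alphabetical one-letter codes).  All
#: in-memory PSSM matrices use this column order so that descriptor names
#: are deterministic regardless of the column order printed in profile files.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Column order printed by PSI-BLAST in its ASCII profile output.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

SS_STATES = "CHE"

#: Maximal solvent-accessible surface area (A^2) per residue in an extended
#: Ala-X-Ala tripeptide (theoretical values of Tien et al. 2013), used to
#: normalize absolute ASA to relative solvent accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

POSITIVE_TOKENS = {"1", "+1", "pos", "positive", "dna-binding", "binding", "yes", "true"}
NEGATIVE_TOKENS = {"0", "-1", "neg", "negative", "non-binding", "non", "no", "false"}

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNKNOWN = "unknown"


class ParseError(ValueError):
    """A file did not conform to the expected dialect."""


@dataclass
class ProteinRecord:
    """One protein chain: identifier, AA sequence and binding label."""

    id: str
    sequence: str
    label: str = LABEL_UNKNOWN
    deposition_date: date | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise ParseError(
                f"record {self.id!r}: sequence contains non-standard "
                f"characters {sorted(bad)} (sequence: {self.sequence})"
            )
        if len(self.sequence) < 60:
            warnings.warn(
                f"record {self.id!r}: chain shorter than 60 residues "
                f"(length {len(self.sequence)})",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMatrix:
    """L x 20 position-specific scoring matrix, canonical column order.

    ``scores`` holds raw log-odds until passed through the logistic
    normalization; ``normalized`` flags which form it is in.
    """

    protein_id: str
    scores: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r} must be L x 20, "
                f"got shape {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"PSSM for {self.protein_id!r} has non-finite entries")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class StructuralProfile:
    """Per-residue 3-state secondary structure and RSA in [0, 1]."""

    protein_id: str
    ss: str
    rsa: np.ndarray

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        if len(self.ss) != self.rsa.shape[0]:
            raise ValueError(
                f"profile for {self.protein_id!r}: ss length {len(self.ss)} "
                f"!= rsa length {self.rsa.shape[0]}"
            )
        bad = set(self.ss) - set(SS_STATES)
        if bad:
            raise ParseError(
                f"profile for {self.protein_id!r}: unknown SS state(s) {sorted(bad)}; "
                f"expected one of {list(SS_STATES)}"
            )
        if np.any((self.rsa < 0) | (self.rsa > 1)):
            warnings.warn(
                f"profile for {self.protein_id!r}: RSA values outside [0, 1] "
                "clamped",
                stacklevel=2,
            )
            self.rsa = np.clip(self.rsa, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.ss)


@dataclass
class FeatureMatrix:
    """Named descriptor matrix: one row per protein, optional labels.

    ``values`` is a DataFrame indexed by protein id with descriptor-name
    columns; ``labels`` (0/1) aligns with the index when present.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate descriptor names: {list(dupes[:5])}")
        if self.labels is not None:
            self.labels = pd.Series(self.labels, index=self.values.index).astype(int)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix carries no labels")
        return self.labels.to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        same_vals = self.values.shape == other.values.shape and bool(
            np.allclose(self.X, other.X)
            and list(self.values.index) == list(other.values.index)
            and list(self.values.columns) == list(other.values.columns)
        )
        if not same_vals:
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        return self.labels is None or bool((self.labels == other.labels).all())


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records with label ``unknown``.

    Sequences are uppercased; any character outside the 20-letter alphabet
    (including 'X') raises :class:`ParseError` citing the record.
    """
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _parse_label(token: str) -> str:
    tok = token.strip().lower()
    if tok in POSITIVE_TOKENS:
        return LABEL_POSITIVE
    if tok in NEGATIVE_TOKENS:
        return LABEL_NEGATIVE
    raise ParseError(
        f"unknown target token {token!r}; accepted positive tokens: "
        f"{sorted(POSITIVE_TOKENS)}, negative tokens: {sorted(NEGATIVE_TOKENS)}"
    )


def read_manifest(path: str | Path) -> list[ProteinRecord]:
    """Read a dataset manifest with columns id, date, target, sequence.

    Tab- or comma-delimited; a header row is optional.  Target tokens are
    mapped to positive/negative labels, deposition dates are parsed when
    present (empty field allowed).
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    sep = "\t" if "\t" in lines[0] else ","
    records = []
    start = 0
    head = [c.strip().lower() for c in lines[0].split(sep)]
    if "id" in head and "sequence" in head:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = [c.strip() for c in line.split(sep)]
        if len(parts) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 fields (id, date, target, "
                f"sequence), got {len(parts)}"
            )
        pid, datestr, target, seq = parts
        dep = date.fromisoformat(datestr) if datestr else None
        records.append(
            ProteinRecord(
                id=pid, sequence=seq, label=_parse_label(target), deposition_date=dep
            )
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate protein ids in manifest")
    return records


def write_manifest(records: Sequence[ProteinRecord], path: str | Path) -> None:
    label_token = {LABEL_POSITIVE: "1", LABEL_NEGATIVE: "0", LABEL_UNKNOWN: ""}
    with open(path, "w") as fh:
        fh.write("id\tdate\ttarget\tsequence\n")
        for rec in records:
            d = rec.deposition_date.isoformat() if rec.deposition_date else ""
            fh.write(f"{rec.id}\t{d}\t{label_token[rec.label]}\t{rec.sequence}\n")


# ---------------------------------------------------------------------------
# PSSM profiles

_AA_LETTER = re.compile(r"^[A-Z]$")


def read_pssm(
    path: str | Path,
    expected_length: int,
    protein_id: str | None = None,
    sequence: str | None = None,
) -> PSSMatrix:
    """Parse a PSI-BLAST ASCII profile into an L x 20 raw-score matrix.

    Only the first 20 score columns (log-odds) are used; the weighted
    percentage columns and information-content trailer are ignored.  The
    column order declared on the file's header line is remapped to the
    canonical alphabetical order :data:`AA_ALPHABET`.

    Parameters
    ----------
    expected_length
        Length of the paired sequence; a differing data-row count raises.
    sequence
        When given, per-row residue letters are cross-checked against it.
    """
    path = Path(path)
    pid = protein_id or path.stem
    col_order: str | None = None
    rows: list[list[int]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            # header line: >=20 single AA letters, no leading position number
            if col_order is None and all(_AA_LETTER.match(t) for t in tokens) and len(tokens) >= 20:
                col_order = "".join(tokens[:20])
                continue
            if tokens[0].isdigit() and len(tokens) >= 22 and _AA_LETTER.match(tokens[1]):
                try:
                    scores = [int(t) for t in tokens[2:22]]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: unparseable score row: {exc}")
                rows.append(scores)
                letters.append(tokens[1])
            elif tokens[0].isdigit():
                raise ParseError(
                    f"{path}:{lineno}: data row with fewer than 20 score columns"
                )
    if col_order is None:
        col_order = PSIBLAST_ORDER
    if sorted(col_order) != sorted(AA_ALPHABET):
        raise ParseError(f"{path}: header does not list the 20 AA types exactly once")
    if len(rows) != expected_length:
        raise ParseError(
            f"{path}: {len(rows)} data rows but expected_length={expected_length}"
        )
    if sequence is not None and "".join(letters) != sequence.upper():
        raise ParseError(f"{path}: residue letters disagree with the paired sequence")
    raw = np.asarray(rows, dtype=float)
    # remap file column order -> canonical alphabetical order
    perm = [col_order.index(aa) for aa in AA_ALPHABET]
    return PSSMatrix(protein_id=pid, scores=raw[:, perm])


def write_pssm(pssm: PSSMatrix, sequence: str, path: str | Path) -> None:
    """Write a raw PSSM in the PSI-BLAST ASCII profile dialect."""
    if pssm.normalized:
        raise ValueError("refusing to write a normalized PSSM as a profile file")
    if len(sequence) != len(pssm):
        raise ValueError("sequence length does not match PSSM row count")
    perm = [AA_ALPHABET.index(aa) for aa in PSIBLAST_ORDER]
    mat = pssm.scores[:, perm].astype(int)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("   " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, mat), start=1):
            fh.write(f"{i:5d} {aa} " + " ".join(f"{v:3d}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# structural profiles


def read_structural_profile(
    path: str | Path,
    expected_length: int,
    protein_id: str | None = None,
    mode: str = "rsa",
) -> StructuralProfile:
    """Read a per-residue table of position, residue, SS state and RSA/ASA.

    Lines starting with '#' are comments.  With ``mode='rsa'`` the fourth
    column is relative solvent accessibility in [0, 1] (values outside are
    clamped with a warning); with ``mode='asa'`` it is absolute accessible
    surface area in A^2 and is divided by the residue's maximal ASA
    (:data:`MAX_ASA`).
    """
    if mode not in ("rsa", "asa"):
        raise ValueError(f"mode must be 'rsa' or 'asa', got {mode!r}")
    path = Path(path)
    pid = protein_id or path.stem
    ss: list[str] = []
    acc: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(tokens)}")
            _, res, state, value = tokens[:4]
            if state not in SS_STATES:
                raise ParseError(
                    f"{path}:{lineno}: unknown SS token {state!r} "
                    f"(3-state {list(SS_STATES)} input required)"
                )
            try:
                v = float(value)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unparseable accessibility: {exc}")
            if mode == "asa":
                if res not in MAX_ASA:
                    raise ParseError(f"{path}:{lineno}: unknown residue {res!r}")
                v = v / MAX_ASA[res]
            ss.append(state)
            acc.append(v)
    if len(ss) != expected_length:
        raise ParseError(
            f"{path}: {len(ss)} data rows but expected_length={expected_length}"
        )
    return StructuralProfile(protein_id=pid, ss="".join(ss), rsa=np.asarray(acc))


def write_structural_profile(
    profile: StructuralProfile, sequence: str, path: str | Path
) -> None:
    if len(sequence) != len(profile):
        raise ValueError("sequence length does not match profile length")
    with open(path, "w") as fh:
        fh.write("# pos res ss rsa\n")
        for i, (aa, state, r) in enumerate(zip(sequence, profile.ss, profile.rsa), 1):
            fh.write(f"{i} {aa} {state} {r:.4f}\n")


# ---------------------------------------------------------------------------
# feature matrices, metric reports


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a TSV: id column, optional label column, one column per descriptor."""
    df = matrix.values.copy()
    if matrix.labels is not None:
        df.insert(0, "label", matrix.labels)
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label")
    return FeatureMatrix(values=df, labels=labels)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
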