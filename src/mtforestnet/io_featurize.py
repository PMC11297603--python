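"""Reading chemical tables, structure filtering, label binarization and
fingerprinting.

A chemical enters the pipeline as a row of a delimited table (CSV/TSV, or a
plain SMILES file) and leaves as a :class:`ChemicalRecord` whose structure
has been validated, deduplicated against the rest of the table by canonical
SMILES, and converted to a fixed-length binary fingerprint (ECFP of diameter
6, i.e. Morgan radius 3, hashed to 1024 bits by default; MACCS keys for
visualization).

Filtering is deliberately conservative: multi-fragment entries (salts,
mixtures) are rejected rather than desalted, because no single desalting
protocol is assumed; rejected rows are reported with a reason instead of
being silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .exceptions import FeaturizationError, SchemaError, ValidationError

RDLogger.DisableLog("rdApp.*")

#: sentinel for a missing binary label / endpoint value
MISSING = None


@dataclass
class ChemicalRecord:
    """One chemical: identifier, structure, raw endpoint values, binary labels.

    ``endpoint_values`` carries raw measurements (units implied by the
    endpoint, e.g. a benchmark dose in mM or a lowest-effect level in µM);
    ``labels`` carries {0, 1} calls or ``None`` for missing.
    """

    chem_id: str
    smiles: str
    endpoint_values: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int | None] = field(default_factory=dict)


@dataclass(frozen=True)
class EndpointRule:
    """Threshold rule turning a raw endpoint value into a toxic/nontoxic call.

    ``direction`` gives the comparison whose satisfaction means *toxic*
    (label 1): ``le`` -> value <= threshold, ``ge`` -> value >= threshold,
    ``gt`` -> value > threshold (strict).
    """

    endpoint_name: str
    threshold: float
    direction: str  # {le, ge, gt}
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("le", "ge", "gt"):
            raise ValidationError(
                f"unknown direction {self.direction!r} for endpoint "
                f"{self.endpoint_name!r}"
            )


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint of a single structure."""

    bits: np.ndarray
    scheme: str  # {ECFP6, MACCS}

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))

    @property
    def length(self) -> int:
        return int(self.bits.shape[0])


@dataclass(frozen=True)
class Reject:
    """A dropped input row and why it was dropped."""

    row: int
    chem_id: str
    reason: str


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".smi", ".smiles"):
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                         comment=None, skip_blank_lines=True)
        df.columns = ["smiles", "chem_id"][: df.shape[1]]
        if "chem_id" not in df.columns:
            df["chem_id"] = [f"row{i}" for i in range(len(df))]
        return df
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_chemical_table(
    path: str | Path,
    column_map: dict[str, object] | None = None,
) -> tuple[list[ChemicalRecord], list[Reject]]:
    """Read a delimited chemical table into records.

    Parameters
    ----------
    path
        CSV/TSV file (delimiter chosen by extension) or plain SMILES file
        (``.smi``: whitespace-separated structure and optional id, no header).
    column_map
        Mapping with keys ``"smiles"`` (required column name), ``"id"``
        (optional; row index used when absent) and ``"endpoints"`` (optional
        list of endpoint columns; defaults to every remaining column).

    Returns
    -------
    (records, rejects)
        One record per usable row; rows with an empty structure cell are
        returned in ``rejects`` tagged ``"no structure"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    column_map = dict(column_map or {})
    smiles_col = column_map.get("smiles", "smiles")
    id_col = column_map.get("id")
    if smiles_col not in df.columns:
        raise SchemaError(f"structure column {smiles_col!r} not in {list(df.columns)}")
    if id_col is not None and id_col not in df.columns:
        raise SchemaError(f"id column {id_col!r} not in {list(df.columns)}")
    endpoint_cols = column_map.get("endpoints")
    if endpoint_cols is None:
        endpoint_cols = [c for c in df.columns if c not in (smiles_col, id_col)]
    else:
        for c in endpoint_cols:
            if c not in df.columns:
                raise SchemaError(f"endpoint column {c!r} not in {list(df.columns)}")

    records: list[ChemicalRecord] = []
    rejects: list[Reject] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        chem_id = str(row[id_col]) if id_col is not None else f"row{i}"
        smiles = row.get(smiles_col)
        if smiles is None or (isinstance(smiles, float) and math.isnan(smiles)) \
                or str(smiles).strip() == "":
            rejects.append(Reject(i, chem_id, "no structure"))
            continue
        values: dict[str, float] = {}
        for c in endpoint_cols:
            v = row.get(c)
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                continue
            try:
                values[c] = float(v)
            except ValueError as exc:
                raise ValidationError(
                    f"non-numeric value {v!r} for endpoint {c!r} in row {i}"
                ) from exc
        records.append(ChemicalRecord(chem_id, str(smiles).strip(), values))
    return records, rejects


def write_chemical_table(records: list[ChemicalRecord], path: str | Path) -> None:
    """Write records back to CSV (inverse of :func:`read_chemical_table`)."""
    path = Path(path)
    endpoints = sorted({e for r in records for e in r.endpoint_values})
    rows = []
    for r in records:
        row = {"chem_id": r.chem_id, "smiles": r.smiles}
        row.update({e: r.endpoint_values.get(e) for e in endpoints})
        rows.append(row)
    pd.DataFrame(rows, columns=["chem_id", "smiles", *endpoints]).to_csv(path, index=False)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None when the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def filter_and_deduplicate(
    records: list[ChemicalRecord],
) -> tuple[list[ChemicalRecord], list[Reject]]:
    """Drop unparseable structures, mixtures, and duplicate structures.

    Duplicates are detected on the canonical structure (two SMILES spellings
    of the same molecule collapse); the first occurrence is kept and later
    ones rejected. A mixture is any multi-fragment structure — no desalting
    is attempted. Kept records preserve first-occurrence order, and
    ``len(kept) + len(rejects) == len(records)``.
    """
    kept: list[ChemicalRecord] = []
    rejects: list[Reject] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        canon = canonical_smiles(rec.smiles)
        if canon is None:
            rejects.append(Reject(i, rec.chem_id, "unparseable structure"))
            continue
        if "." in canon:
            rejects.append(Reject(i, rec.chem_id, "mixture"))
            continue
        if canon in seen:
            rejects.append(Reject(i, rec.chem_id, "duplicate"))
            continue
        seen.add(canon)
        kept.append(rec)
    return kept, rejects


def write_rejects_report(rejects: list[Reject], path: str | Path) -> None:
    """CSV report of dropped rows: (row, chem_id, reason)."""
    pd.DataFrame(
        [(r.row, r.chem_id, r.reason) for r in rejects],
        columns=["row", "chem_id", "reason"],
    ).to_csv(path, index=False)


def binarize_endpoint(value: float | None, rule: EndpointRule) -> int | None:
    """Apply a threshold rule; missing value propagates as missing label.

    Comparisons follow the rule's printed operator exactly: ``le``/``ge``
    are inclusive, ``gt`` is strict.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"non-numeric value {value!r} for endpoint {rule.endpoint_name!r}"
        ) from exc
    if rule.direction == "le":
        return int(v <= rule.threshold)
    if rule.direction == "ge":
        return int(v >= rule.threshold)
    return int(v > rule.threshold)


_MORGAN_CACHE: dict[tuple[int, int], object] = {}


def featurize(
    smiles: str,
    scheme: str = "ECFP6",
    n_bits: int = 1024,
    radius: int = 3,
) -> Fingerprint:
    """Compute a binary fingerprint for one structure.

    ECFP of diameter 6 corresponds to Morgan *radius* 3 (toolkits
    parameterize by radius; the diameter is twice the radius). MACCS keys
    ignore ``n_bits``/``radius`` and always yield RDKit's 167-bit vector.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"invalid structure: {smiles!r}")
    if scheme == "ECFP6":
        key = (radius, n_bits)
        gen = _MORGAN_CACHE.get(key)
        if gen is None:
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
            _MORGAN_CACHE[key] = gen
        bits = np.zeros(n_bits, dtype=np.uint8)
        for b in gen.GetFingerprint(mol).GetOnBits():
            bits[b] = 1
    elif scheme == "MACCS":
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(fp.GetNumBits(), dtype=np.uint8)
        for b in fp.GetOnBits():
            bits[b] = 1
    else:
        raise ValidationError(f"unknown fingerprint scheme {scheme!r}")
    return Fingerprint(bits, scheme)


def featurize_records(
    records: list[ChemicalRecord],
    scheme: str = "ECFP6",
    n_bits: int = 1024,
    radius: int = 3,
) -> tuple[np.ndarray, list[str]]:
    """Fingerprint a record list into an (n_chemicals, n_bits) uint8 matrix."""
    mats = [featurize(r.smiles, scheme, n_bits, radius).bits for r in records]
    return np.vstack(mats) if mats else np.zeros((0, n_bits), np.uint8), [
        r.chem_id for r in records
    ]
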