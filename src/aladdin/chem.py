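"""Compound I/O, fingerprint featurization, chemical similarity and dataset splitting.

Compounds are either real molecules (SMILES, featurized with RDKit) or
abstract library members carrying precomputed ``raw`` feature vectors, so
that the synthetic benchmark can exercise the full screening pipeline
without any chemistry.
"""

from __future__ import annotations

import csv as _csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Activity",
    "FeatureVector",
    "CompoundRecord",
    "StructureEntry",
    "read_compound_library",
    "featurize",
    "featurize_smiles",
    "tanimoto",
    "bulk_tanimoto",
    "split_train_test",
    "filter_test_by_train_similarity",
]

BINARY_KINDS = frozenset({"hashed_circular", "structural_keys"})
DESCRIPTOR_KINDS = frozenset({"hashed_circular", "structural_keys", "physchem_2d", "raw"})


class Activity(str, Enum):
    """Activity class of a library compound: experimentally active or presumed-inactive decoy."""

    ACTIVE = "active"
    DECOY = "decoy"


@dataclass
class FeatureVector:
    """A molecular descriptor vector.

    Parameters
    ----------
    kind:
        One of ``hashed_circular`` (Morgan/ECFP-style hashed circular
        fingerprint; the default is radius 2, 1024 bits), ``structural_keys``
        (MACCS, 167 bits), ``physchem_2d`` (RDKit's 2D physicochemical
        descriptor set, standing in for proprietary 2D descriptor suites) or
        ``raw`` (caller-supplied vector, used by the synthetic benchmark).
    values:
        Numeric vector; binary (0/1) for the two fingerprint kinds.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in DESCRIPTOR_KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("feature vector must be a non-empty 1-D array")
        if self.kind in BINARY_KINDS and not np.isin(self.values, (0, 1)).all():
            raise ValueError(f"{self.kind} fingerprints must be binary")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class CompoundRecord:
    """One library molecule with its activity class.

    ``representations`` holds alternative molecular structures of the same
    compound (tautomers/protomers) as ``(representation_id, smiles)`` pairs;
    docking scores obtained for different representations are later collapsed
    to one score per compound.  For abstract synthetic compounds ``smiles``
    is ``None`` and ``features`` carries a ``raw`` vector.
    """

    compound_id: str
    activity_class: Activity
    smiles: str | None = None
    representations: list[tuple[str, str]] = field(default_factory=list)
    features: FeatureVector | None = None

    def __post_init__(self) -> None:
        self.activity_class = Activity(self.activity_class)
        if self.smiles is not None and not self.representations:
            self.representations = [(f"{self.compound_id}/0", self.smiles)]
        if self.smiles is None and self.representations:
            raise ValueError("representations given without a SMILES")


@dataclass(frozen=True)
class StructureEntry:
    """One protein structure of the docking ensemble.

    The co-crystallized ligand (SMILES, or a raw fingerprint in the synthetic
    benchmark) is required only by the similarity-based structure-selection
    baseline; structures without one simply cannot be chosen by that baseline.
    """

    structure_id: str
    cocrystal_ligand_smiles: str | None = None
    cocrystal_ligand_features: FeatureVector | None = None


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def _mol_from_smiles(smiles: str):
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles)


def featurize_smiles(
    smiles: str,
    kind: str = "hashed_circular",
    *,
    radius: int = 2,
    n_bits: int = 1024,
) -> FeatureVector:
    """Featurize a single SMILES string.

    Deterministic: the SMILES is canonicalized by RDKit during parsing, so
    aliases of the same molecule yield bitwise-identical vectors.
    """
    if kind not in DESCRIPTOR_KINDS or kind == "raw":
        raise ValueError(f"cannot featurize SMILES with kind {kind!r}")
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if kind == "hashed_circular":
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        return FeatureVector(kind, np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8))
    if kind == "structural_keys":
        from rdkit.Chem import MACCSkeys

        bv = MACCSkeys.GenMACCSKeys(mol)
        return FeatureVector(kind, np.asarray(list(bv), dtype=np.uint8))
    # physchem_2d: RDKit's full 2D descriptor set (~210 descriptors), a
    # documented open substitute for proprietary 2D descriptor suites.
    try:
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("descriptor backend unavailable for physchem_2d") from exc
    values = Descriptors.CalcMolDescriptors(mol)
    ordered = [values[name] for name in sorted(values)]
    return FeatureVector("physchem_2d", np.asarray(ordered, dtype=float))


def featurize(
    compound: CompoundRecord,
    kind: str = "hashed_circular",
    *,
    radius: int = 2,
    n_bits: int = 1024,
) -> FeatureVector:
    """Featurize a compound; ``raw`` returns its stored vector unchanged."""
    if kind == "raw":
        if compound.features is None or compound.features.kind != "raw":
            raise ValueError(f"compound {compound.compound_id} has no raw feature vector")
        return compound.features
    if compound.smiles is None:
        raise ValueError(f"compound {compound.compound_id} has no SMILES to featurize")
    return featurize_smiles(compound.smiles, kind, radius=radius, n_bits=n_bits)


def feature_matrix(
    compounds: Sequence[CompoundRecord],
    kind: str = "hashed_circular",
    *,
    radius: int = 2,
    n_bits: int = 1024,
) -> np.ndarray:
    """Stack per-compound feature vectors into an ``(n, L)`` float array."""
    rows = [featurize(c, kind, radius=radius, n_bits=n_bits).values for c in compounds]
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def tanimoto(a: FeatureVector | np.ndarray, b: FeatureVector | np.ndarray) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| between two binary vectors.

    Returns 1.0 when both vectors are empty (no set bits) — the documented
    convention so that identical compounds always score 1.
    """
    va = a.values if isinstance(a, FeatureVector) else np.asarray(a)
    vb = b.values if isinstance(b, FeatureVector) else np.asarray(b)
    if isinstance(a, FeatureVector) and isinstance(b, FeatureVector) and a.kind != b.kind:
        raise ValueError(f"fingerprint kinds differ: {a.kind} vs {b.kind}")
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint lengths differ: {va.size} vs {vb.size}")
    va = va.astype(bool)
    vb = vb.astype(bool)
    union = np.logical_or(va, vb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(va, vb).sum() / union)


def bulk_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between the rows of two binary matrices."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint lengths differ")
    inter = A.astype(np.float64) @ B.astype(np.float64).T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return tc


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def _parse_activity(value: str) -> Activity:
    v = str(value).strip().lower()
    if v in {"active", "1", "true"}:
        return Activity.ACTIVE
    if v in {"decoy", "inactive", "0", "false"}:
        return Activity.DECOY
    raise ValueError(f"unrecognized activity class {value!r}")


def _rows_from_smiles_table(path: Path) -> Iterable[dict]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"smiles_table row needs >= 3 fields: {line!r}")
            row = {"smiles": parts[0], "compound_id": parts[1], "activity_class": parts[2]}
            if len(parts) > 3:
                row["representation_id"] = parts[3]
            yield row


def _rows_from_csv(path: Path) -> Iterable[dict]:
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None or not {"smiles", "compound_id", "activity_class"} <= set(
            reader.fieldnames
        ):
            raise ValueError("CSV needs header with smiles, compound_id, activity_class")
        yield from reader


def _rows_from_sdf(path: Path, activity_field: str) -> Iterable[dict]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield {"smiles": None, "compound_id": f"<sdf:{i}>", "activity_class": None}
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        if not mol.HasProp(activity_field):
            raise ValueError(f"SDF record {cid} lacks activity field {activity_field!r}")
        yield {
            "smiles": Chem.MolToSmiles(mol),
            "compound_id": cid,
            "activity_class": mol.GetProp(activity_field),
        }


def read_compound_library(
    path: str | Path,
    format: str = "smiles_table",
    *,
    activity_field: str = "activity_class",
) -> list[CompoundRecord]:
    """Read a compound library with activity classes.

    Supported formats: ``smiles_table`` (whitespace-delimited columns
    ``smiles compound_id activity_class [representation_id]``), ``csv``
    (header row required) and ``sdf`` (activity in a named property field).
    Rows sharing a ``compound_id`` but carrying distinct ``representation_id``
    values are merged into one record with several representations.

    Rows whose SMILES RDKit cannot parse are skipped with a logged warning;
    duplicate (compound_id, representation_id) pairs are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "smiles_table":
        rows = _rows_from_smiles_table(path)
    elif format == "csv":
        rows = _rows_from_csv(path)
    elif format == "sdf":
        rows = _rows_from_sdf(path, activity_field)
    else:
        raise ValueError(f"unknown library format {format!r}")

    records: dict[str, CompoundRecord] = {}
    seen_reps: set[tuple[str, str]] = set()
    n_skipped = 0
    for row in rows:
        smiles = row.get("smiles")
        cid = str(row["compound_id"])
        if smiles is None or _mol_from_smiles(smiles) is None:
            n_skipped += 1
            logger.warning("skipping %s: unparseable structure", cid)
            continue
        rep_id = str(row.get("representation_id") or f"{cid}/0")
        if (cid, rep_id) in seen_reps:
            raise ValueError(f"duplicate compound/representation id: {cid}/{rep_id}")
        seen_reps.add((cid, rep_id))
        activity = _parse_activity(row["activity_class"])
        if cid in records:
            rec = records[cid]
            if rec.activity_class != activity:
                raise ValueError(f"conflicting activity classes for {cid}")
            rec.representations.append((rep_id, smiles))
        else:
            records[cid] = CompoundRecord(
                compound_id=cid,
                activity_class=activity,
                smiles=smiles,
                representations=[(rep_id, smiles)],
            )
    if n_skipped:
        logger.warning("skipped %d unparseable rows in %s", n_skipped, path.name)
    return list(records.values())


# ---------------------------------------------------------------------------
# Splitting and similarity filtering
# ---------------------------------------------------------------------------

def split_train_test(
    library: Sequence[CompoundRecord],
    test_fraction: float = 0.2,
    seed: int | None = 0,
) -> dict[str, str]:
    """Stratified train/test assignment, ``{compound_id: "train"|"test"}``.

    Stratification is by activity class so the test set preserves the
    active/decoy ratio; deterministic given ``seed``.
    """
    from sklearn.model_selection import train_test_split

    if not library:
        raise ValueError("empty library")
    ids = [c.compound_id for c in library]
    strata = [c.activity_class.value for c in library]
    for cls in set(strata):
        if strata.count(cls) < 2:
            raise ValueError(f"cannot stratify: class {cls!r} has < 2 members")
    train_ids, test_ids = train_test_split(
        ids, test_size=test_fraction, random_state=seed, stratify=strata
    )
    out = {cid: "train" for cid in train_ids}
    out.update({cid: "test" for cid in test_ids})
    return out


def filter_test_by_train_similarity(
    test: Sequence[CompoundRecord],
    train: Sequence[CompoundRecord],
    cutoff: float,
    *,
    kind: str = "hashed_circular",
    radius: int = 2,
    n_bits: int = 1024,
    inclusive: bool = True,
) -> list[CompoundRecord]:
    """Keep test compounds whose maximum Tanimoto similarity to *any* train
    compound is at most ``cutoff`` (``<`` instead of ``<=`` with
    ``inclusive=False``).

    Used to build test subsets of decreasing structural relatedness to the
    training data; the subset is monotonically nested as the cutoff drops.
    """
    if not train:
        raise ValueError("empty train set")
    if not test:
        return []
    A = feature_matrix(test, kind, radius=radius, n_bits=n_bits) > 0
    B = feature_matrix(train, kind, radius=radius, n_bits=n_bits) > 0
    max_tc = bulk_tanimoto(A, B).max(axis=1)
    if inclusive:
        keep = max_tc <= cutoff
    else:
        keep = max_tc < cutoff
    return [c for c, k in zip(test, keep) if k]
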