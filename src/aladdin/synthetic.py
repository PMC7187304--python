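"""Synthetic virtual-screening benchmark with planted structure preferences.

The generator emulates the statistical structure that machine-learning-
guided structure selection exploits, without any docking engine or real
chemistry:

* compounds fall into feature-space clusters (binary "fingerprints" with
  cluster-specific signature bits);
* each cluster has exactly one *compatible* protein structure (the planted
  map); actives dock well (latent affinity ``active_affinity``) only on
  their compatible structure;
* decoys occasionally acquire a spuriously favorable score on a random
  structure (probability ``decoy_spurious_prob`` per structure) — the
  mechanism behind the well-known false-positive accumulation of
  all-against-all ensemble docking, where taking the best score over many
  structures inflates decoys via an extreme-value effect;
* observed scores are the negated latent affinity plus Gaussian noise
  (lower = more favorable, binding-free-energy-like units).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import Activity, CompoundRecord, FeatureVector, StructureEntry

__all__ = [
    "SyntheticBenchSpec",
    "PlantedTruth",
    "SyntheticBenchmark",
    "SyntheticDockingBackend",
    "generate_library",
    "simulate_scores",
    "generate_benchmark",
    "benchmark_methods",
    "BenchmarkResult",
]


@dataclass(frozen=True)
class SyntheticBenchSpec:
    """Parameters of the synthetic benchmark (defaults are the benchmark
    conditions used throughout the tests).

    Affinities are in the same arbitrary lower-is-better score units as the
    emitted docking scores; ``noise_sd`` is the score noise in those units.
    """

    n_structures: int = 10
    n_clusters: int = 10
    n_actives: int = 200
    n_decoys: int = 2000
    n_bits: int = 1024
    n_signature_bits: int = 40
    p_signature_on: float = 0.9  # signature bit, compound inside the cluster
    p_signature_off: float = 0.05  # signature bit, compound outside the cluster
    p_background: float = 0.02  # non-signature bit
    active_affinity: float = 4.0  # active on its compatible structure
    baseline_affinity: float = 0.0
    decoy_spurious_prob: float = 0.05  # per (decoy, structure)
    decoy_spurious_affinity: float = 3.0
    noise_sd: float = 1.0
    seed: int = 7
    cluster_structure_map: tuple[int, ...] | None = None  # cluster -> structure index

    def __post_init__(self) -> None:
        for name in ("n_structures", "n_clusters", "n_actives", "n_decoys", "n_bits",
                     "n_signature_bits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_signature_on", "p_signature_off", "p_background",
                     "decoy_spurious_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_clusters * self.n_signature_bits > self.n_bits:
            raise ValueError("not enough bits for disjoint cluster signatures")
        if self.cluster_structure_map is None and self.n_clusters > self.n_structures:
            raise ValueError(
                "more clusters than structures: supply an explicit cluster_structure_map"
            )
        if self.cluster_structure_map is not None and (
            len(self.cluster_structure_map) != self.n_clusters
            or not all(0 <= s < self.n_structures for s in self.cluster_structure_map)
        ):
            raise ValueError("cluster_structure_map must give a valid structure per cluster")

    def structure_id(self, i: int) -> str:
        return f"S{i:03d}"

    @property
    def planted_map(self) -> dict[int, str]:
        if self.cluster_structure_map is not None:
            return {k: self.structure_id(s) for k, s in enumerate(self.cluster_structure_map)}
        return {k: self.structure_id(k) for k in range(self.n_clusters)}


@dataclass
class PlantedTruth:
    """Ground truth of a generated benchmark: per-compound cluster and
    compatible structure, plus the latent affinity of every
    (compound, structure) pair (including decoy spurious affinities)."""

    cluster_of: dict[str, int]
    compatible_structure: dict[str, str]
    affinity: pd.DataFrame = field(repr=False)  # compounds x structures


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_library(
    spec: SyntheticBenchSpec,
) -> tuple[list[CompoundRecord], PlantedTruth]:
    """Generate the compound library (raw binary feature vectors) and the
    planted truth, deterministically from the spec's seed."""
    rng_assign, rng_feat, rng_aff = _substreams(spec.seed, 3)

    n_total = spec.n_actives + spec.n_decoys
    compound_ids = [f"A{i:05d}" for i in range(spec.n_actives)] + [
        f"D{i:05d}" for i in range(spec.n_decoys)
    ]
    activities = [Activity.ACTIVE] * spec.n_actives + [Activity.DECOY] * spec.n_decoys
    clusters = rng_assign.integers(0, spec.n_clusters, size=n_total)

    # disjoint cluster signature bit blocks
    bit_perm = rng_feat.permutation(spec.n_bits)
    signature_bits = {
        k: bit_perm[k * spec.n_signature_bits : (k + 1) * spec.n_signature_bits]
        for k in range(spec.n_clusters)
    }
    p = np.full((n_total, spec.n_bits), spec.p_background)
    for k in range(spec.n_clusters):
        p[:, signature_bits[k]] = spec.p_signature_off
    for i in range(n_total):
        p[i, signature_bits[int(clusters[i])]] = spec.p_signature_on
    bits = (rng_feat.random((n_total, spec.n_bits)) < p).astype(np.uint8)

    planted = spec.planted_map
    structure_ids = [spec.structure_id(s) for s in range(spec.n_structures)]
    affinity = np.full((n_total, spec.n_structures), spec.baseline_affinity, dtype=float)
    sid_index = {sid: j for j, sid in enumerate(structure_ids)}
    spurious = rng_aff.random((n_total, spec.n_structures)) < spec.decoy_spurious_prob
    for i in range(n_total):
        if activities[i] is Activity.ACTIVE:
            affinity[i, sid_index[planted[int(clusters[i])]]] = spec.active_affinity
        else:
            affinity[i, spurious[i]] = spec.decoy_spurious_affinity

    compounds = [
        CompoundRecord(
            compound_id=cid,
            activity_class=act,
            features=FeatureVector("raw", bits[i]),
        )
        for i, (cid, act) in enumerate(zip(compound_ids, activities))
    ]
    truth = PlantedTruth(
        cluster_of={cid: int(clusters[i]) for i, cid in enumerate(compound_ids)},
        compatible_structure={
            cid: planted[int(clusters[i])] for i, cid in enumerate(compound_ids)
        },
        affinity=pd.DataFrame(affinity, index=compound_ids, columns=structure_ids),
    )
    return compounds, truth


def simulate_scores(
    spec: SyntheticBenchSpec,
    library: Sequence[CompoundRecord],
    truth: PlantedTruth,
):
    """Docking score matrix: score(c, s) = -affinity(c, s) + N(0, noise_sd)."""
    from .scores import ScoreMatrix

    ids = [c.compound_id for c in library]
    aff = truth.affinity.loc[ids]
    rng_noise = _substreams(spec.seed, 4)[3]
    noise = rng_noise.normal(0.0, spec.noise_sd, size=aff.shape) if spec.noise_sd > 0 else 0.0
    frame = -aff + noise
    return ScoreMatrix(frame=frame)


def sample_cocrystal_structures(
    spec: SyntheticBenchSpec,
    library: Sequence[CompoundRecord],
    truth: PlantedTruth,
) -> list[StructureEntry]:
    """Structure entries whose "co-crystallized ligand" fingerprint is one
    active sampled from the structure's compatible cluster (the synthetic
    analogue of the ligand-similarity baseline's input).  Structures with no
    compatible cluster get no ligand."""
    rng = _substreams(spec.seed, 5)[4]
    by_structure: dict[str, list[CompoundRecord]] = {}
    for c in library:
        if c.activity_class is Activity.ACTIVE:
            by_structure.setdefault(truth.compatible_structure[c.compound_id], []).append(c)
    entries = []
    for s in range(spec.n_structures):
        sid = spec.structure_id(s)
        pool = by_structure.get(sid, [])
        ligand = None
        if pool:
            ligand = pool[int(rng.integers(0, len(pool)))].features
        entries.append(StructureEntry(structure_id=sid, cocrystal_ligand_features=ligand))
    return entries


@dataclass
class SyntheticBenchmark:
    spec: SyntheticBenchSpec
    compounds: list[CompoundRecord]
    truth: PlantedTruth
    structures: list[StructureEntry]
    matrix: "object"  # ScoreMatrix

    @property
    def classes(self) -> dict[str, Activity]:
        return {c.compound_id: c.activity_class for c in self.compounds}


def generate_benchmark(spec: SyntheticBenchSpec) -> SyntheticBenchmark:
    """Library + planted truth + structures + simulated score matrix."""
    compounds, truth = generate_library(spec)
    matrix = simulate_scores(spec, compounds, truth)
    structures = sample_cocrystal_structures(spec, compounds, truth)
    return SyntheticBenchmark(spec, compounds, truth, structures, matrix)


class SyntheticDockingBackend:
    """Live synthetic docking engine.

    Pure function of (compound, structure, backend config): the score is the
    negated planted affinity plus Gaussian noise whose seed is derived from
    the compound and structure ids, so repeated calls agree.
    """

    def __init__(self, spec: SyntheticBenchSpec, truth: PlantedTruth, seed: int | None = None):
        self.spec = spec
        self.truth = truth
        self.seed = spec.seed if seed is None else seed

    def dock(self, compound: CompoundRecord, structure: StructureEntry) -> float | None:
        cid, sid = compound.compound_id, structure.structure_id
        if cid not in self.truth.affinity.index or sid not in self.truth.affinity.columns:
            return None
        aff = float(self.truth.affinity.at[cid, sid])
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(cid.encode()), zlib.crc32(sid.encode())])
        )
        return -aff + float(rng.normal(0.0, self.spec.noise_sd)) if self.spec.noise_sd > 0 else -aff


# ---------------------------------------------------------------------------
# Plain-text export / import (CLI `simulate` dialect)
# ---------------------------------------------------------------------------

def _bits_to_str(values: np.ndarray) -> str:
    return "".join("1" if v else "0" for v in np.asarray(values).astype(int))


def write_benchmark(bench: SyntheticBenchmark, out_dir) -> None:
    """Write a generated benchmark as plain text: ``library.csv`` (with a
    bit-string feature column), ``scores.csv`` (long score dialect),
    ``structures.csv`` (ligand bit-strings) and ``truth.csv``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in bench.compounds],
            "activity_class": [c.activity_class.value for c in bench.compounds],
            "features": [_bits_to_str(c.features.values) for c in bench.compounds],
        }
    ).to_csv(out / "library.csv", index=False)
    bench.matrix.to_csv(out / "scores.csv")
    pd.DataFrame(
        {
            "structure_id": [s.structure_id for s in bench.structures],
            "cocrystal_ligand_features": [
                _bits_to_str(s.cocrystal_ligand_features.values)
                if s.cocrystal_ligand_features is not None
                else ""
                for s in bench.structures
            ],
        }
    ).to_csv(out / "structures.csv", index=False)
    pd.DataFrame(
        {
            "compound_id": list(bench.truth.cluster_of),
            "cluster": list(bench.truth.cluster_of.values()),
            "compatible_structure": [
                bench.truth.compatible_structure[cid] for cid in bench.truth.cluster_of
            ],
        }
    ).to_csv(out / "truth.csv", index=False)


def read_raw_library(path) -> list[CompoundRecord]:
    """Read a raw-feature library CSV written by :func:`write_benchmark`."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    return [
        CompoundRecord(
            compound_id=row.compound_id,
            activity_class=Activity(row.activity_class),
            features=FeatureVector(
                "raw", np.frombuffer(row.features.encode(), dtype=np.uint8) - ord("0")
            ),
        )
        for row in df.itertuples()
    ]


def read_raw_structures(path) -> list[StructureEntry]:
    """Read a structures CSV written by :func:`write_benchmark`."""
    df = pd.read_csv(path, dtype={"structure_id": str})
    out = []
    for row in df.itertuples():
        feats = None
        bits = getattr(row, "cocrystal_ligand_features", "")
        if isinstance(bits, str) and bits:
            feats = FeatureVector("raw", np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
        out.append(StructureEntry(structure_id=row.structure_id, cocrystal_ligand_features=feats))
    return out


# ---------------------------------------------------------------------------
# End-to-end benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Outcome of one full pipeline run on a generated benchmark."""

    reports: dict  # method -> EvalReport (aladdin, similarity, ensemble)
    single_auc: dict[str, float]  # per-structure single-structure AUC
    mean_single_auc: float
    recovery_fraction: float  # test actives whose selected structure is the planted one
    selection_balance: pd.DataFrame
    grid: "object"
    battery: "object"
    screens: dict
    split: dict[str, str]
    test_ids: list[str]


def benchmark_methods(
    spec: SyntheticBenchSpec = SyntheticBenchSpec(),
    seed: int | None = None,
    *,
    grid=None,
    cv_folds: int = 5,
    test_fraction: float = 0.2,
    ef_fractions: Sequence[float] = (0.01, 0.05, 0.10),
) -> BenchmarkResult:
    """Run the full pipeline on one generated benchmark and compare methods.

    Steps: generate -> stratified split -> per-structure rank labeling on
    the training split -> cross-validated model selection -> SMOTE-balanced
    battery training -> screening of the test split with aladdin,
    similarity, ensemble and every single-structure protocol -> metrics.

    ``seed`` drives the split/CV/SMOTE/forest randomness (defaults to the
    spec's generation seed); generation itself is always governed by
    ``spec.seed``.  The default grid is a single preselected cell
    (raw descriptors, 500 trees, sqrt max_features); pass the
    full :class:`~aladdin.battery.HyperparameterGrid` to re-run the whole
    exploration.
    """
    from .battery import CorrectnessBattery, HyperparameterGrid, SimilarityStructureSelector, grid_search_cv
    from .chem import feature_matrix, split_train_test
    from .labeling import assign_correctness_labels
    from .metrics import evaluate_hitlist
    from .scores import rank_compounds
    from .screen import run_screen

    if seed is None:
        seed = spec.seed
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31 - 1)
    bench = generate_benchmark(spec)
    classes = bench.classes

    split = split_train_test(bench.compounds, test_fraction, seed=int(seeds[0]))
    train = [c for c in bench.compounds if split[c.compound_id] == "train"]
    test = [c for c in bench.compounds if split[c.compound_id] == "test"]
    train_ids = [c.compound_id for c in train]
    test_ids = [c.compound_id for c in test]

    train_matrix = bench.matrix.restrict(train_ids)
    label_cols = {}
    for sid in train_matrix.structure_ids:
        hits = rank_compounds(train_matrix, sid)
        labels = assign_correctness_labels(hits, classes, structure_id=sid)
        label_cols[sid] = labels.label_array(train_ids)
    Y = pd.DataFrame(label_cols, index=train_ids)

    X_train = feature_matrix(train, "raw")
    X_test = feature_matrix(test, "raw")

    if grid is None:
        grid = HyperparameterGrid(
            descriptor_kinds=("raw",), n_estimators=(500,), max_features=("sqrt",)
        )
    grid_result = grid_search_cv(
        {k: X_train for k in grid.descriptor_kinds}, Y, grid, k_folds=cv_folds, seed=int(seeds[1])
    )

    battery = CorrectnessBattery(
        n_estimators=grid_result.n_estimators,
        max_features=grid_result.max_features,
        use_smote=True,
        random_state=int(seeds[2]),
    ).fit(X_train, Y)
    retained = battery.structure_ids_

    ligand_fps, ligand_sids = [], []
    for s in bench.structures:
        if s.structure_id in retained and s.cocrystal_ligand_features is not None:
            ligand_fps.append(s.cocrystal_ligand_features.values)
            ligand_sids.append(s.structure_id)
    similarity = SimilarityStructureSelector().fit(np.asarray(ligand_fps), ligand_sids)

    common = dict(matrix=bench.matrix, structure_ids=retained, features=X_test)
    screens = {
        "aladdin": run_screen("aladdin", test, battery=battery, **common),
        "similarity": run_screen("similarity", test, similarity=similarity, **common),
        "ensemble": run_screen("ensemble", test, **common),
    }
    for sid in retained:
        screens[f"single:{sid}"] = run_screen(f"single:{sid}", test, **common)

    reports = {
        m: evaluate_hitlist(
            m, r.hits, classes, ef_fractions=ef_fractions, assignments=r.assignments
        )
        for m, r in screens.items()
    }
    single_auc = {
        sid: reports[f"single:{sid}"].auc for sid in retained
    }

    test_actives = [c.compound_id for c in test if c.activity_class is Activity.ACTIVE]
    selected = {a.compound_id: a.structure_id for a in screens["aladdin"].assignments}
    hitcount = sum(
        1 for cid in test_actives if selected[cid] == bench.truth.compatible_structure[cid]
    )
    recovery = hitcount / len(test_actives) if test_actives else float("nan")

    from .metrics import selection_diagnostics

    balance = selection_diagnostics(screens["aladdin"].assignments, classes)

    return BenchmarkResult(
        reports={m: reports[m] for m in ("aladdin", "similarity", "ensemble")},
        single_auc=single_auc,
        mean_single_auc=float(np.mean(list(single_auc.values()))),
        recovery_fraction=float(recovery),
        selection_balance=balance,
        grid=grid_result,
        battery=battery,
        screens=screens,
        split=split,
        test_ids=test_ids,
    )
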