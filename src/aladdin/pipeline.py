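"""Two-phase pipeline orchestration: train the classifier battery, then
apply it (screen compound sets with the requested methods).

All randomness flows from one global seed via named per-stage substreams
(split, cross-validation, SMOTE/forests, scrambling), so every stage is
independently reproducible; every output manifest records the seeds and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .battery import (
    CorrectnessBattery,
    GridSearchResult,
    HyperparameterGrid,
    SimilarityStructureSelector,
    grid_search_cv,
    save_battery,
)
from .chem import (
    Activity,
    CompoundRecord,
    StructureEntry,
    feature_matrix,
    filter_test_by_train_similarity,
    read_compound_library,
    split_train_test,
)
from .labeling import assign_correctness_labels
from .metrics import EvalReport, evaluate_hitlist
from .scores import ScoreMatrix, rank_compounds
from .screen import run_screen
from .synthetic import read_raw_library, read_raw_structures

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "TrainingResult", "run_training_phase", "run_application_phase"]

_STAGES = ("split", "cv", "fit", "scramble")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full train/apply run."""

    library: str
    scores: str
    out_dir: str
    structures: str | None = None
    library_format: str = "smiles_table"  # smiles_table | csv | sdf | raw_csv
    fingerprint: dict = field(
        default_factory=lambda: {"kind": "hashed_circular", "radius": 2, "n_bits": 1024}
    )
    test_fraction: float = 0.2
    cv_folds: int = 10
    smote_k_neighbors: int = 5
    grid: dict | None = None  # axes of HyperparameterGrid; None = selected setup
    ef_fractions: tuple = (0.01, 0.05, 0.10)
    similarity_cutoffs: tuple = (0.8, 0.7)
    methods: tuple = ("aladdin", "similarity", "ensemble")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for name in ("library", "scores"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.structures is not None and not Path(self.structures).exists():
            raise FileNotFoundError(f"structures path does not exist: {self.structures}")
        if "similarity" in self.methods and self.structures is None:
            raise ValueError("method 'similarity' requested but no structures file given")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES)) % (2**31 - 1)
        return {name: int(s) for name, s in zip(_STAGES, state)}

    def hyperparameter_grid(self) -> HyperparameterGrid:
        if self.grid is None:
            kind = self.fingerprint.get("kind", "hashed_circular")
            return HyperparameterGrid(
                descriptor_kinds=(kind,), n_estimators=(500,), max_features=("sqrt",)
            )
        return HyperparameterGrid(
            descriptor_kinds=tuple(self.grid.get("descriptor_kinds", ("hashed_circular",))),
            n_estimators=tuple(self.grid.get("n_estimators", (50, 100, 500))),
            max_features=tuple(
                None if mf in ("None", "none") else mf
                for mf in self.grid.get("max_features", ("sqrt", 0.2, 0.4, 0.6, 0.8, None))
            ),
        )


def _load_library(config: PipelineConfig) -> list[CompoundRecord]:
    if config.library_format == "raw_csv":
        return read_raw_library(config.library)
    return read_compound_library(config.library, config.library_format)


def _load_structures(config: PipelineConfig) -> list[StructureEntry]:
    if config.structures is None:
        return []
    df = pd.read_csv(config.structures, dtype=str)
    if "cocrystal_ligand_features" in df.columns:
        return read_raw_structures(config.structures)
    out = []
    for row in df.itertuples():
        smiles = getattr(row, "cocrystal_ligand_smiles", None)
        out.append(
            StructureEntry(
                structure_id=row.structure_id,
                cocrystal_ligand_smiles=smiles if isinstance(smiles, str) and smiles else None,
            )
        )
    return out


def _features(config: PipelineConfig, compounds: Sequence[CompoundRecord]) -> np.ndarray:
    fp = config.fingerprint
    return feature_matrix(
        compounds,
        fp.get("kind", "hashed_circular"),
        radius=int(fp.get("radius", 2)),
        n_bits=int(fp.get("n_bits", 1024)),
    )


@dataclass
class TrainingResult:
    battery: CorrectnessBattery
    grid: GridSearchResult
    split: dict[str, str]
    label_frame: pd.DataFrame = field(repr=False)
    manifest: dict = field(repr=False)


def run_training_phase(config: PipelineConfig) -> TrainingResult:
    """Execute the training phase: label the training split per structure,
    select the modeling setup by cross-validated MCC, fit the SMOTE-balanced
    battery and persist it with a manifest."""
    config.validate()
    seeds = config.stage_seeds()
    compounds = _load_library(config)
    classes = {c.compound_id: c.activity_class for c in compounds}
    matrix = ScoreMatrix.from_csv(config.scores)

    known = set(matrix.compound_ids)
    missing = [c.compound_id for c in compounds if c.compound_id not in known]
    if missing:
        raise ValueError(
            f"training phase: {len(missing)} library compounds have no score rows "
            f"(e.g. {missing[:3]})"
        )

    split = split_train_test(compounds, config.test_fraction, seed=seeds["split"])
    train = [c for c in compounds if split[c.compound_id] == "train"]
    train_ids = [c.compound_id for c in train]
    train_matrix = matrix.restrict(train_ids)

    label_cols = {}
    for sid in train_matrix.structure_ids:
        labels = assign_correctness_labels(rank_compounds(train_matrix, sid), classes, sid)
        balance = np.mean(labels.label_array(train_ids))
        logger.info("structure %s: n_actives=%d, fraction correct=%.3f", sid, labels.n_actives, balance)
        label_cols[sid] = labels.label_array(train_ids)
    label_frame = pd.DataFrame(label_cols, index=train_ids)

    grid = config.hyperparameter_grid()
    features_by_kind = {
        kind: (
            feature_matrix(train, "raw")
            if kind == "raw"
            else feature_matrix(
                train,
                kind,
                radius=int(config.fingerprint.get("radius", 2)),
                n_bits=int(config.fingerprint.get("n_bits", 1024)),
            )
        )
        for kind in grid.descriptor_kinds
    }
    grid_result = grid_search_cv(
        features_by_kind, label_frame, grid, k_folds=config.cv_folds, seed=seeds["cv"]
    )
    logger.info(
        "selected setup: %s, %d trees, max_features=%s (CV MCC %.3f +/- %.3f)",
        grid_result.descriptor_kind, grid_result.n_estimators, grid_result.max_features,
        grid_result.mean_mcc, grid_result.std_mcc,
    )

    battery = CorrectnessBattery(
        n_estimators=grid_result.n_estimators,
        max_features=grid_result.max_features,
        use_smote=True,
        smote_k_neighbors=config.smote_k_neighbors,
        random_state=seeds["fit"],
    ).fit(features_by_kind[grid_result.descriptor_kind], label_frame)

    manifest = {
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "selected_setup": {
            "descriptor_kind": grid_result.descriptor_kind,
            "n_estimators": int(grid_result.n_estimators),
            "max_features": grid_result.max_features,
            "cv_mean_mcc": round(grid_result.mean_mcc, 6),
            "cv_std_mcc": round(grid_result.std_mcc, 6),
        },
        "n_train": len(train_ids),
        "n_test": len(compounds) - len(train_ids),
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_battery(
        battery,
        out / "battery",
        fingerprint_config=config.fingerprint,
        cv_table=grid_result.table,
        extra_manifest=manifest,
    )
    split_frame = pd.DataFrame(sorted(split.items()), columns=["compound_id", "subset"])
    split_frame.to_csv(out / "split.csv", index=False)
    return TrainingResult(battery, grid_result, split, label_frame, manifest)


def run_application_phase(
    config: PipelineConfig,
    training: TrainingResult,
) -> dict[str, dict[str, EvalReport]]:
    """Screen the held-out test set (and its similarity-filtered subsets)
    with every requested method; write metric and ROC tables.

    Returns ``{subset_name: {method: EvalReport}}`` with subsets ``test``,
    ``subset1`` (max train Tc <= first cutoff), ``subset2`` (second cutoff).
    """
    config.validate()
    compounds = _load_library(config)
    classes = {c.compound_id: c.activity_class for c in compounds}
    matrix = ScoreMatrix.from_csv(config.scores)
    battery = training.battery
    if battery.n_features_in_ != _features(config, compounds[:1]).shape[1]:
        raise ValueError("battery/config fingerprint mismatch: feature lengths differ")

    split = training.split
    train = [c for c in compounds if split[c.compound_id] == "train"]
    test = [c for c in compounds if split[c.compound_id] == "test"]

    fp_kind = config.fingerprint.get("kind", "hashed_circular")
    subsets: dict[str, list[CompoundRecord]] = {"test": test}
    for i, cutoff in enumerate(config.similarity_cutoffs, start=1):
        subsets[f"subset{i}"] = filter_test_by_train_similarity(
            test,
            train,
            cutoff,
            kind=fp_kind,
            radius=int(config.fingerprint.get("radius", 2)),
            n_bits=int(config.fingerprint.get("n_bits", 1024)),
        )

    similarity = None
    if "similarity" in config.methods:
        structures = [
            s
            for s in _load_structures(config)
            if s.structure_id in set(battery.structure_ids_)
        ]
        fps, sids = [], []
        for s in structures:
            if s.cocrystal_ligand_features is not None:
                fps.append(s.cocrystal_ligand_features.values)
                sids.append(s.structure_id)
            elif s.cocrystal_ligand_smiles is not None:
                from .chem import featurize_smiles

                fps.append(
                    featurize_smiles(
                        s.cocrystal_ligand_smiles,
                        fp_kind,
                        radius=int(config.fingerprint.get("radius", 2)),
                        n_bits=int(config.fingerprint.get("n_bits", 1024)),
                    ).values
                )
                sids.append(s.structure_id)
        if not fps:
            raise ValueError("similarity method requested but no co-crystal ligands available")
        similarity = SimilarityStructureSelector().fit(np.asarray(fps), sids)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_reports: dict[str, dict[str, EvalReport]] = {}
    rows = []
    for name, members in subsets.items():
        if not members:
            logger.warning("subset %s is empty; skipped", name)
            continue
        X = _features(config, members)
        reports = {}
        for method in config.methods:
            result = run_screen(
                method,
                members,
                battery=battery if method == "aladdin" else None,
                similarity=similarity if method == "similarity" else None,
                matrix=matrix,
                structure_ids=battery.structure_ids_,
                features=X,
            )
            rep = evaluate_hitlist(
                method, result.hits, classes,
                ef_fractions=config.ef_fractions, assignments=result.assignments,
            )
            reports[method] = rep
            row = {"subset": name, **rep.to_row()}
            rows.append(row)
            fpr, tpr = rep.roc_points
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                out / f"roc_{name}_{method.replace(':', '_')}.csv", index=False
            )
            result.assignments_frame().to_csv(
                out / f"assignments_{name}_{method.replace(':', '_')}.csv", index=False
            )
        all_reports[name] = reports
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    return all_reports
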