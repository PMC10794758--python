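"""End-to-end orchestration: features -> combo -> balance -> model -> metrics.

The workflow mirrors how the classifier is meant to be benchmarked:

1. label two FASTA record sets (lncRNA = 0, mRNA = 1) and pool them;
2. stratified train/test split (default 80/20, seeded);
3. compute the five feature families, fitting the composition PCA on
   TRAINING rows only and transforming held-out rows with the frozen model;
4. assemble one of the 16 named combinations;
5. balance the training rows (undersample / SMOTE / none) in the assembled
   feature space — the evaluation split is never balanced;
6. train the BCE classifier and score the held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import balance as balance_mod
from . import combos, composition, mlp, periodicity, physchem
from .evalstats import MetricsReport, classification_metrics
from .seqio import SeqRecord


@dataclass
class FeatureStore:
    """Per-family feature matrices plus labels, all aligned by sequence id."""

    families: dict[str, pd.DataFrame]
    labels: pd.Series
    pca_models: dict[str, composition.PCAModel] = field(default_factory=dict)

    def subset(self, ids) -> "FeatureStore":
        return FeatureStore(
            families={k: v.loc[ids] for k, v in self.families.items()},
            labels=self.labels.loc[ids],
            pca_models=self.pca_models,
        )


def raw_feature_frames(
    records: list[SeqRecord],
    energy_di: physchem.EnergyTable | None = None,
    energy_tri: physchem.EnergyTable | None = None,
    weighting: str = "empirical",
) -> dict[str, pd.DataFrame]:
    """BP/DP/TP features plus raw composition matrices (comp2, comp3).

    Missing energy tables fall back to the bundled illustrative ones.
    """
    energy_di = energy_di or physchem.example_energy_table(2)
    energy_tri = energy_tri or physchem.example_energy_table(3)
    return {
        "BP": periodicity.bp_features(records),
        "DP": physchem.energy_feature_frame(records, energy_di, "dp", weighting),
        "TP": physchem.energy_feature_frame(records, energy_tri, "tp", weighting),
        "comp2": composition.composition_matrix(records, 2),
        "comp3": composition.composition_matrix(records, 3),
    }


def build_feature_store(
    records: list[SeqRecord],
    train_ids,
    n_components: int = composition.DEFAULT_N_COMPONENTS,
    energy_di: physchem.EnergyTable | None = None,
    energy_tri: physchem.EnergyTable | None = None,
    weighting: str = "empirical",
) -> FeatureStore:
    """Compute all five families; composition PCA is fit on ``train_ids`` only."""
    if any(r.label is None for r in records):
        raise ValueError("all records must be labelled")
    raw = raw_feature_frames(records, energy_di, energy_tri, weighting)
    labels = pd.Series(
        [r.label for r in records], index=[r.id for r in records], name="label"
    )
    pca_models: dict[str, composition.PCAModel] = {}
    families = {k: raw[k] for k in ("BP", "DP", "TP")}
    for family, key, prefix in (("DC", "comp2", "dc_pc"), ("TC", "comp3", "tc_pc")):
        comp = raw[key]
        model = composition.fit_pca(comp.loc[train_ids].values, n_components)
        pca_models[family] = model
        families[family] = composition.transform(model, comp, prefix=prefix)
    return FeatureStore(families=families, labels=labels, pca_models=pca_models)


@dataclass
class RunResult:
    combo: str
    balance_method: str
    seed: int
    model: mlp.TrainedModel
    metrics: MetricsReport
    train_ids: list[str]
    test_ids: list[str]
    provenance: dict[str, str]
    n_synthetic: int


def train_evaluate(
    records: list[SeqRecord],
    combo: str | combos.ComboSpec,
    balance_method: str = "smote",
    seed: int = 0,
    test_frac: float = 0.2,
    k_neighbors: int = 5,
    n_components: int = composition.DEFAULT_N_COMPONENTS,
    energy_di: physchem.EnergyTable | None = None,
    energy_tri: physchem.EnergyTable | None = None,
    weighting: str = "empirical",
    mlp_config: mlp.MLPConfig | None = None,
) -> RunResult:
    """Run the full benchmark protocol for one feature combination."""
    combo_spec = combos.get_combo(combo) if isinstance(combo, str) else combo
    if any(r.label is None for r in records):
        raise ValueError("all records must be labelled")
    labels = np.array([r.label for r in records])
    ids = np.array([r.id for r in records])
    train_idx, test_idx = mlp.stratified_split(labels, test_frac=test_frac, seed=seed)
    train_ids, test_ids = ids[train_idx], ids[test_idx]

    store = build_feature_store(
        records, train_ids, n_components=n_components,
        energy_di=energy_di, energy_tri=energy_tri, weighting=weighting,
    )
    matrix, provenance = combos.assemble(combo_spec, store.families)
    y = store.labels

    X_train = matrix.loc[train_ids].values
    y_train = y.loc[train_ids].values
    X_test = matrix.loc[test_ids].values
    y_test = y.loc[test_ids].values

    balanced = balance_mod.balance(
        X_train, y_train, method=balance_method, seed=seed, k_neighbors=k_neighbors
    )

    if mlp_config is None:
        mlp_config = mlp.MLPConfig(input_dim=matrix.shape[1], seed=seed)
    elif mlp_config.input_dim != matrix.shape[1]:
        raise ValueError(
            f"mlp_config.input_dim={mlp_config.input_dim} but combo "
            f"{combo_spec.name} yields {matrix.shape[1]} features"
        )
    model = mlp.train(balanced.X, balanced.y.astype(float), mlp_config)
    probs = mlp.predict_proba(model, X_test)
    metrics = classification_metrics(y_test, probs)
    return RunResult(
        combo=combo_spec.name,
        balance_method=balance_method,
        seed=seed,
        model=model,
        metrics=metrics,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        provenance=provenance,
        n_synthetic=balanced.n_synthetic,
    )


def paired_balance_report(records, combo, seed=0, **kwargs) -> dict[str, MetricsReport]:
    """Metrics with SMOTE and with undersampling, side by side.

    Mirrors the reporting convention 'smote/undersample' for each metric.
    """
    return {
        method: train_evaluate(records, combo, balance_method=method, seed=seed, **kwargs).metrics
        for method in ("smote", "undersample")
    }
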