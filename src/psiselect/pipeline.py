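"""End-to-end orchestration: epochs -> band networks -> feature table ->
screening -> multi-objective subset selection -> report.

The selection stage follows the model/results idiom: a
:class:`FeatureSelectionModel` is built from a labeled feature table
(:class:`~psiselect.objectives.Dataset`), ``fit()`` runs one or more of the
search algorithms, and the returned :class:`SelectionResults` carries the
non-dominated sets, decoded feature names, per-solution error rates and a
``summary()`` table.  The earlier stages (feature-table construction, the
one-way-ANOVA screen, the single-feature classification matrix) are plain
functions, since nothing is estimated there.

Feature-table column order is band-major — delta block first, gamma last,
each block in the canonical 14-feature order — matching the 14/70-bit
particle layout of the selection stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import DEFAULT_TAU, binarize, connectivity_matrix
from .graph_features import FEATURE_NAMES, NullEnsembleSpec, feature_vector
from .objectives import Dataset, SubsetEvaluator, cv_error
from .optimizer import ALGORITHMS, OptimizerConfig, RunResult, decode, run
from .preprocessing import BAND_ORDER, bandpass
from .synthetic import LabeledEpochs

__all__ = [
    "build_feature_table",
    "anova_screen",
    "single_feature_table",
    "FeatureSelectionProblem",
    "FeatureSelectionModel",
    "SelectionResults",
    "run_selection",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

ANOVA_ALPHA = 0.01


def minmax_normalize(table: np.ndarray) -> np.ndarray:
    """Column-wise min-max scaling to [0, 1]; constant columns map to 0."""
    x = np.asarray(table, dtype=float)
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0.0] = 1.0
    return (x - lo) / span


def build_feature_table(
    epochs: LabeledEpochs,
    tau: float = DEFAULT_TAU,
    ens: NullEnsembleSpec = NullEnsembleSpec(),
    bands: tuple[str, ...] = BAND_ORDER,
) -> Dataset:
    """One row per epoch, 14 columns per band in band-major order.

    Each epoch is band-filtered, converted to a thresholded binary network,
    and summarized by the 14 topology features.  The null-ensemble seed is
    re-derived per (epoch, band) from ``ens.seed`` so rows are independent
    of processing order and the whole table is reproducible.
    """
    rows = []
    for eid, epoch in zip(epochs.epoch_ids, epochs.epochs):
        row = []
        for bi, band in enumerate(bands):
            try:
                ble = bandpass(epoch, epochs.fs, band, epoch_id=eid)
                net = binarize(connectivity_matrix(ble), tau)
                sub_seed = int(
                    np.random.SeedSequence(entropy=ens.seed, spawn_key=(eid, bi))
                    .generate_state(1)[0] % (2**31 - 1)
                )
                sub_ens = NullEnsembleSpec(ens.n_random, ens.rewires_per_edge, sub_seed)
                row.extend(feature_vector(net, sub_ens))
            except Exception as exc:
                raise RuntimeError(f"feature extraction failed for epoch {eid}, band {band}") from exc
        rows.append(row)
    names = [f"{band}:{feat}" for band in bands for feat in FEATURE_NAMES]
    return Dataset(np.asarray(rows), np.asarray(epochs.groups), names)


def anova_screen(ds: Dataset, alpha: float = ANOVA_ALPHA) -> pd.DataFrame:
    """One-way ANOVA of each (band, feature) column across the two groups.

    Columns are min-max normalized first (screening operates on the same
    [0, 1] scale used for feature visualization).  Returns a DataFrame with
    F, p and a significance flag at ``p < alpha``; a zero-variance column
    gets p = 1 with a warning.
    """
    x = minmax_normalize(ds.table)
    labels = ds.binary_labels()
    out = []
    for j, name in enumerate(ds.feature_names):
        a = x[labels == 0, j]
        b = x[labels == 1, j]
        if np.ptp(x[:, j]) == 0.0:
            logger.warning("zero-variance column %s: p set to 1", name)
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(a, b)
        out.append({"feature": name, "F": float(f_stat), "p": float(p),
                    "significant": bool(p < alpha)})
    return pd.DataFrame(out)


def single_feature_table(
    ds: Dataset, scheme: str = "kfold10", seed: int = 0, classifier: str = "svm"
) -> pd.DataFrame:
    """Cross-validated error of each single feature on its own, arranged as
    a band x feature matrix (the screening companion to subset search)."""
    bands = list(dict.fromkeys(n.split(":")[0] for n in ds.feature_names))
    table = pd.DataFrame(index=bands, columns=list(FEATURE_NAMES), dtype=float)
    for j, name in enumerate(ds.feature_names):
        band, feat = name.split(":")
        mask = np.zeros(ds.n_features, dtype=bool)
        mask[j] = True
        table.loc[band, feat] = cv_error(ds, mask, classifier, scheme, seed)
    return table


@dataclass
class FeatureSelectionProblem:
    """Adapter putting a feature table behind the optimizer protocol:
    unit-cube positions decode to masks by threshold, objectives come from
    the memoizing subset evaluator."""

    evaluator: SubsetEvaluator
    decode_threshold: float = 0.5
    n_objectives: int = 4

    @property
    def dimension(self) -> int:
        return self.evaluator.ds.n_features

    def mask_of(self, u: np.ndarray) -> np.ndarray:
        return decode(u, self.decode_threshold)

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        return self.evaluator(self.mask_of(u).astype(bool)).as_array()


def _solution_frame(res: RunResult, problem: FeatureSelectionProblem, ds: Dataset) -> pd.DataFrame:
    rows = []
    for pos, objs in zip(res.archive.positions, res.archive._objs):
        mask = problem.mask_of(pos)
        names = [ds.feature_names[i] for i in np.flatnonzero(mask)]
        f1, f2, f3, f4 = objs
        rows.append(
            {
                "algorithm": res.algorithm,
                "mask": "".join(map(str, mask)),
                "features": "-".join(names),
                "n_features": int(mask.sum()),
                "F1_svm": f1,
                "F2_nb": f2,
                "F3_da": f3,
                "F4_distance": f4,
                "mean_error_3": (f1 + f2 + f3) / 3.0,
                "mean_error_4": (f1 + f2 + f3 + f4) / 4.0,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["mean_error_3", "n_features", "mask"], kind="stable"
        ).reset_index(drop=True)
    return frame


@dataclass
class SelectionResults:
    """Fitted results of a feature-subset search.

    ``solutions`` holds every archived non-dominated subset per algorithm
    with its four objectives; ``best`` is the minimum mean-of-three-errors
    row per algorithm (the headline each search reports).
    """

    model: "FeatureSelectionModel"
    runs: dict[str, RunResult]
    solutions: pd.DataFrame
    distinct_masks: dict[str, int]

    @property
    def best(self) -> pd.DataFrame:
        return (
            self.solutions.loc[
                self.solutions.groupby("algorithm")["mean_error_3"].idxmin()
            ]
            .sort_values("mean_error_3", kind="stable")
            .reset_index(drop=True)
        )

    def best_mask(self, algorithm: str) -> np.ndarray:
        row = self.solutions[self.solutions.algorithm == algorithm].iloc[0]
        return np.array([int(b) for b in row["mask"]])

    def revalidate(self, scheme: str = "loo") -> pd.DataFrame:
        """Re-evaluate each algorithm's best subset under another
        cross-validation scheme (e.g. leave-one-out)."""
        from .objectives import evaluate_subset

        rows = []
        for alg in self.solutions.algorithm.unique():
            mask = self.best_mask(alg).astype(bool)
            vec = evaluate_subset(self.model.ds, mask, scheme, self.model.seed)
            rows.append(
                {
                    "algorithm": alg,
                    "scheme": scheme,
                    "F1_svm": vec.f1,
                    "F2_nb": vec.f2,
                    "F3_da": vec.f3,
                    "mean_error_3": vec.mean_error,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Feature-subset selection results",
            "=" * 60,
            f"samples: {self.model.ds.n_samples}   features: {self.model.ds.n_features}   "
            f"cv: {self.model.scheme}   seed: {self.model.seed}",
            "",
            "Best subset per algorithm (min mean error of SVM/NB/DA):",
        ]
        for _, row in self.best.iterrows():
            lines.append(
                f"  {row.algorithm:10s} mean_err={row.mean_error_3:.4f} "
                f"(svm {row.F1_svm:.4f}, nb {row.F2_nb:.4f}, da {row.F3_da:.4f}) "
                f"n={row.n_features:2d}  {row.features}"
            )
        lines.append("")
        lines.append("Distinct feature combinations evaluated:")
        for alg, k in self.distinct_masks.items():
            lines.append(f"  {alg:10s} {k}")
        return "\n".join(lines)


@dataclass
class FeatureSelectionModel:
    """Wrapper tying a labeled feature table to the subset-search machinery.

    ``fit`` runs the requested algorithms (fresh, seeded evaluators per
    algorithm so runs are independent) and returns
    :class:`SelectionResults`.
    """

    ds: Dataset
    scheme: str = "kfold10"
    seed: int = 0
    config: OptimizerConfig = field(default_factory=OptimizerConfig)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, label_col: str = "group", **kwargs
    ) -> "FeatureSelectionModel":
        cols = [c for c in frame.columns if c not in (label_col, "epoch_id")]
        ds = Dataset(frame[cols].to_numpy(dtype=float), frame[label_col].to_numpy(), cols)
        return cls(ds, **kwargs)

    def fit(self, algorithms: tuple[str, ...] = ("mopso_gdm",)) -> SelectionResults:
        runs: dict[str, RunResult] = {}
        frames = []
        distinct: dict[str, int] = {}
        for alg in algorithms:
            if alg not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {alg!r}")
            evaluator = SubsetEvaluator(self.ds, self.scheme, self.seed)
            problem = FeatureSelectionProblem(evaluator, self.config.decode_threshold)
            cfg = OptimizerConfig(**{**self.config.__dict__, "seed": self.seed})
            res = run(alg, problem, cfg)
            runs[alg] = res
            distinct[alg] = evaluator.n_distinct_masks
            frames.append(_solution_frame(res, problem, self.ds))
        solutions = pd.concat(frames, ignore_index=True)
        return SelectionResults(self, runs, solutions, distinct)


def run_selection(
    ds: Dataset,
    algorithms: tuple[str, ...] = ALGORITHMS,
    cfg: OptimizerConfig | None = None,
    scheme: str = "kfold10",
    seed: int = 0,
) -> SelectionResults:
    """Functional entry point over :class:`FeatureSelectionModel`."""
    model = FeatureSelectionModel(ds, scheme, seed, cfg or OptimizerConfig())
    return model.fit(algorithms)


def run_pipeline(
    out_dir: str | Path,
    *,
    epochs: LabeledEpochs | None = None,
    synthetic_spec=None,
    tau: float = DEFAULT_TAU,
    ens: NullEnsembleSpec | None = None,
    algorithms: tuple[str, ...] = ("mopso_gdm",),
    cfg: OptimizerConfig | None = None,
    scheme: str = "kfold10",
    seed: int = 0,
    revalidate_loo: bool = False,
) -> Path:
    """Full run: (simulate ->) features -> screen -> select -> report.

    One top-level seed fixes the synthetic data, the null ensembles, the
    folds and the optimizer; two invocations with the same arguments write
    byte-identical artifacts.  Intermediate tables are cached as CSV inside
    ``out_dir`` so later stages can be re-run from them.
    """
    from .io import write_feature_table
    from .synthetic import generate_coupled_epochs

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if epochs is None:
        if synthetic_spec is None:
            raise ValueError("provide epochs or a synthetic spec")
        epochs = generate_coupled_epochs(synthetic_spec)
    ens = ens or NullEnsembleSpec(seed=seed)

    ds = build_feature_table(epochs, tau, ens)
    write_feature_table(out_dir / "feature_table.csv", ds)

    screen = anova_screen(ds)
    screen.to_csv(out_dir / "anova_screen.csv", index=False)

    singles = single_feature_table(ds, scheme, seed)
    singles.to_csv(out_dir / "single_feature_errors.csv")

    results = run_selection(ds, algorithms, cfg, scheme, seed)
    results.solutions.to_csv(out_dir / "pareto_solutions.csv", index=False)
    results.best.to_csv(out_dir / "best_subsets.csv", index=False)
    if revalidate_loo:
        results.revalidate("loo").to_csv(out_dir / "loo_revalidation.csv", index=False)

    manifest = {
        "seed": seed,
        "tau": tau,
        "scheme": scheme,
        "algorithms": list(algorithms),
        "n_samples": ds.n_samples,
        "n_features": ds.n_features,
        "ensemble": {"n_random": ens.n_random, "rewires_per_edge": ens.rewires_per_edge,
                     "seed": ens.seed},
        "optimizer": {k: (v if not isinstance(v, np.generic) else v.item())
                      for k, v in (cfg or OptimizerConfig()).__dict__.items()},
        "distinct_masks": results.distinct_masks,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out_dir / "report.txt").write_text(results.summary() + "\n")
    return out_dir
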