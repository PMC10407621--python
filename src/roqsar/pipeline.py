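"""End-to-end study orchestration: descriptors -> select -> train -> evaluate -> AD."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ann, dataset as ds, descriptors, evaluation, feature_selection, mlr
from .exceptions import RoqsarError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "roqsar_run"
    input_csv: str | None = None  # dataset CSV; default: packaged fixture
    split_mode: str = "fixed_fixture"  # or "random"
    seed: int = 1
    response: str = "experimental"
    k_select: int = 4
    corr_threshold: float = 0.90
    entry_alpha: float = 0.05
    train: ann.TrainConfig = field(default_factory=ann.TrainConfig)

    def as_dict(self) -> dict:
        return asdict(self)


def _random_splits(index, seed: int) -> pd.Series:
    """Seeded random partition at the study's split fractions."""
    n = len(index)
    n_test = round(0.1527 * n)
    n_val = round(0.1527 * n)
    labels = np.array(["training"] * (n - n_test - n_val)
                      + ["test"] * n_test + ["validation"] * n_val)
    rng = np.random.default_rng(seed)
    return pd.Series(labels[rng.permutation(n)], index=index, name="split")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_fixture_dataset(response: str = "experimental",
                          embed_seed: int = 2023) -> ds.QsarDataset:
    """Descriptor table + responses for the packaged 72-compound study data."""
    from . import molgraph

    records = ds.load_fixture()
    mols = [molgraph.parse_structure(r.smiles, name=r.name, abbrev=r.abbrev)
            for r in records]
    table = descriptors.descriptor_table(mols, embed_seed=embed_seed)
    return ds.assemble(records, table, response=response)


def run_study(config: RunConfig) -> Path:
    """Run the full pipeline, writing every artifact plus a manifest.

    Any stage failure aborts with the stage name in the exception message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "assembly"
    try:
        if config.input_csv is None:
            data = build_fixture_dataset(response=config.response,
                                         embed_seed=config.seed + 2022)
        else:
            data = ds.read_csv(config.input_csv)
        if config.split_mode == "random":
            data = ds.QsarDataset(data.X, data.y,
                                  _random_splits(data.X.index, config.seed),
                                  data.censored, data.meta)
        desc_path = out / "descriptors.csv"
        data.X.assign(compound=data.X.index).set_index("compound").to_csv(
            desc_path, float_format="%.10g")
        ds.write_csv(data, out / "dataset.csv")

        stage = "selection"
        if data.X.shape[1] <= config.k_select:
            # nothing to select from (e.g. the fixture ships the four
            # already-selected descriptors); keep all columns
            logger.info("selection skipped: %d columns <= k=%d",
                        data.X.shape[1], config.k_select)
            report = feature_selection.SelectionReport(
                n_input=data.X.shape[1], zero_variance_removed=[],
                correlation_removed=[], stepwise_ranking=[],
                selected=list(data.X.columns))
            X_sel = data.X
        else:
            report, X_sel = feature_selection.run_cascade(
                data.X, data.y, k=config.k_select,
                corr_threshold=config.corr_threshold, entry_alpha=config.entry_alpha)
        (out / "selection_report.json").write_text(
            json.dumps(report.as_dict(), indent=1))
        data_sel = ds.QsarDataset(X_sel, data.y, data.splits, data.censored, data.meta)

        stage = "training"
        cfg = ann.TrainConfig(**{**asdict(config.train),
                                 "topology": (X_sel.shape[1],
                                              config.train.topology[1], 1),
                                 "seed": config.seed})
        result = ann.train(data_sel, cfg)
        ann.save_result(result, out / "model.json")
        result.history.to_csv(out / "history.csv", index=False,
                              float_format="%.10g")
        ann.effective_weight_table(result).to_csv(
            out / "effective_weights.csv", float_format="%.10g")

        stage = "evaluation"
        y_pred = pd.Series(ann.predict(result, data_sel.X.to_numpy(dtype=float)),
                           index=data_sel.X.index)
        y_pred.rename("prediction").to_csv(out / "predictions.csv",
                                           float_format="%.10g")
        metrics = evaluation.metrics_by_split(data_sel.y, y_pred, data_sel.splits)
        (out / "metrics.json").write_text(json.dumps(
            {k: m.as_dict() for k, m in metrics.items()}, indent=1))

        stage = "mlr"
        mlr_model = mlr.fit_mlr(data_sel.X, data_sel.y)
        mlr_pred = pd.Series(mlr.predict(mlr_model, data_sel.X),
                             index=data_sel.X.index)
        mlr_metrics = evaluation.metrics_by_split(data_sel.y, mlr_pred,
                                                  data_sel.splits)
        (out / "mlr.json").write_text(json.dumps(
            {"model": mlr_model.as_dict(),
             "metrics": {k: m.as_dict() for k, m in mlr_metrics.items()}},
            indent=1))

        stage = "applicability_domain"
        report_ad, williams = evaluation.williams_report(y_pred, data_sel)
        williams.to_csv(out / "williams.tsv", sep="\t", index=False,
                        float_format="%.10g")
    except RoqsarError as exc:
        raise RoqsarError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": config.as_dict(),
        "stop_reason": result.stop_reason,
        "epochs_run": result.epochs_run,
        "selected_descriptors": report.selected,
        "ad_outliers": report_ad.outliers,
        "h_star": report_ad.h_star,
        "checksums": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def hidden_node_sweep(data: ds.QsarDataset, node_range=range(1, 8),
                      seed: int = 1, max_epochs: int = 300) -> pd.DataFrame:
    """Train one model per hidden-node count; report test-split MSE.

    Rows are sorted by node count; the minimum test MSE marks the selected
    architecture.
    """
    rows = []
    for n_hidden in sorted(node_range):
        cfg = ann.TrainConfig(topology=(data.X.shape[1], n_hidden, 1),
                              seed=seed, max_epochs=max_epochs)
        result = ann.train(data, cfg)
        test = data.subset("test")
        y_pred = ann.predict(result, test.X.to_numpy(dtype=float))
        metrics = evaluation.fit_metrics(test.y.to_numpy(), y_pred, scope="test")
        rows.append({"n_hidden": n_hidden, "test_mse": metrics.mse,
                     "test_r2": metrics.r2, "stop_reason": result.stop_reason})
    frame = pd.DataFrame(rows)
    frame["selected"] = frame["test_mse"] == frame["test_mse"].min()
    return frame
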