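"""Synthetic QSAR-like datasets with known ground truth.

Generated tables plant the structures the filtering cascade assumes:
zero-variance columns, near-duplicate column pairs (|r| > 0.95), a small
set of informative descriptors, and a bounded nonlinear response in
[0, 100] with additive noise.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ann import AnnWeights, logsig
from .dataset import QsarDataset

logger = logging.getLogger(__name__)

#: default split fractions (training, test, validation)
DEFAULT_FRACTIONS = (0.6944, 0.1527, 0.1529)


@dataclass
class SyntheticSpec:
    n_compounds: int = 200
    n_informative: int = 4
    n_noise: int = 10
    n_zero_variance: int = 3
    n_duplicate_pairs: int = 3
    response_kind: str = "hidden_network"
    noise_sd: float = 3.0
    split_fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-6:
            raise ValueError("split fractions must sum to 1")
        if min(self.n_compounds, self.n_informative) < 0 or \
                min(self.n_noise, self.n_zero_variance, self.n_duplicate_pairs) < 0:
            raise ValueError("counts must be non-negative")
        if self.response_kind not in ("linear", "hidden_network"):
            raise ValueError(f"unknown response_kind {self.response_kind!r}")


@dataclass
class GroundTruth:
    informative_names: list[str]
    generator_weights: AnnWeights | np.ndarray
    noise_sd: float
    spec: SyntheticSpec = field(default=None)

    def as_dict(self) -> dict:
        gw = (self.generator_weights.as_dict()
              if isinstance(self.generator_weights, AnnWeights)
              else np.asarray(self.generator_weights).tolist())
        return {"informative_names": self.informative_names,
                "generator_weights": gw, "noise_sd": self.noise_sd,
                "spec": asdict(self.spec) if self.spec else None}


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_test = round(fractions[1] * n)
    n_val = round(fractions[2] * n)
    n_train = n - n_test - n_val
    if n > 0 and min(n_train, n_test, n_val) < 1:
        raise ValueError(f"n_compounds={n} too small for fractions {fractions}")
    return n_train, n_test, n_val


def _draw_generator(spec: SyntheticSpec, rng: np.random.Generator):
    if spec.response_kind == "linear":
        return rng.uniform(2.0, 8.0, size=spec.n_informative) * rng.choice(
            [-1.0, 1.0], size=spec.n_informative)
    n_hidden = 4
    W = rng.uniform(-2.5, 2.5, size=(spec.n_informative, n_hidden))
    b_hidden = rng.uniform(-1.0, 1.0, size=n_hidden)
    v = rng.uniform(-3.5, 3.5, size=n_hidden)
    # centre the pre-sigmoid output (hidden activations average ~0.5) so the
    # bounded response spans a wide range instead of saturating
    return AnnWeights(W=W, b_hidden=b_hidden, v=v, b_out=float(-0.5 * v.sum()))


def _draw_dataset(spec: SyntheticSpec, generator, data_seed) -> QsarDataset:
    rng = np.random.default_rng(data_seed)
    n = spec.n_compounds
    inf_names = [f"INF{i + 1}" for i in range(spec.n_informative)]
    noise_names = [f"NOISE{i + 1}" for i in range(spec.n_noise)]
    columns: dict[str, np.ndarray] = {}
    for name in inf_names + noise_names:
        columns[name] = rng.standard_normal(n)
    # near-duplicates of existing columns: jitter sized for |r| > 0.95.
    # Noise columns are preferred as sources so the planted correlated
    # pairs do not shadow the informative signal.
    base_names = noise_names if noise_names else inf_names
    for i in range(spec.n_duplicate_pairs):
        src = base_names[i % len(base_names)]
        columns[f"DUP{i + 1}_{src}"] = columns[src] + 0.2 * rng.standard_normal(n)
    for i in range(spec.n_zero_variance):
        columns[f"ZV{i + 1}"] = np.full(n, float(i))  # includes an all-zero column
    X = pd.DataFrame(columns, index=[f"synth{i + 1}" for i in range(n)])

    X_inf = X[inf_names].to_numpy() if inf_names else np.zeros((n, 0))
    if spec.response_kind == "linear":
        y_clean = 50.0 + X_inf @ np.asarray(generator)
    else:
        # inset the bounded response by ~2 noise sd so additive noise rarely
        # crosses [0, 100]; keeps the clipping rate below ~2%
        margin = min(2.0 * spec.noise_sd, 10.0)
        hidden = logsig(X_inf @ generator.W + generator.b_hidden)
        y_clean = margin + (100.0 - 2.0 * margin) * logsig(
            hidden @ generator.v + generator.b_out)
    y = y_clean + spec.noise_sd * rng.standard_normal(n)
    clipped = (y < 0) | (y > 100)
    if clipped.any():
        rate = clipped.mean()
        (logger.warning if rate > 0.02 else logger.info)(
            "clipping %.1f%% of responses to [0, 100]", 100 * rate)
    y = np.clip(y, 0.0, 100.0)

    n_train, n_test, n_val = _split_sizes(n, spec.split_fractions)
    labels = np.array(["training"] * n_train + ["test"] * n_test
                      + ["validation"] * n_val)
    labels = labels[rng.permutation(n)]
    return QsarDataset(
        X=X, y=pd.Series(y, index=X.index, name="response"),
        splits=pd.Series(labels, index=X.index, name="split"),
        meta={"synthetic": True, "seed": spec.seed},
    )


def generate(spec: SyntheticSpec) -> tuple[QsarDataset, GroundTruth]:
    """Draw a dataset and its ground truth from the seeded mechanism."""
    ss = np.random.SeedSequence(spec.seed)
    weight_seed, data_seed = ss.spawn(2)
    generator = _draw_generator(spec, np.random.default_rng(weight_seed))
    dataset = _draw_dataset(spec, generator, data_seed)
    truth = GroundTruth(
        informative_names=[f"INF{i + 1}" for i in range(spec.n_informative)],
        generator_weights=generator, noise_sd=spec.noise_sd, spec=spec,
    )
    return dataset, truth


def regenerate(truth: GroundTruth, n: int, draw: int = 1) -> QsarDataset:
    """Fresh dataset from the same mechanism (same generator weights).

    Each ``draw`` index yields an independent derived seed.
    """
    if truth.spec is None:
        raise ValueError("GroundTruth carries no generating spec")
    spec = SyntheticSpec(**{**asdict(truth.spec), "n_compounds": n})
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + draw)
    if n == 0:
        empty = pd.DataFrame(
            {c: pd.Series(dtype=float) for c in
             truth.informative_names
             + [f"NOISE{i + 1}" for i in range(spec.n_noise)]})
        return QsarDataset(empty, pd.Series(dtype=float),
                           pd.Series(dtype=object), pd.Series(dtype=bool))
    return _draw_dataset(spec, truth.generator_weights, children[1 + draw])
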