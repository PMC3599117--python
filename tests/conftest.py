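from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import crossarray as ca


def make_dataset(values, features=None, samples=None, **kwargs):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    kwargs.setdefault("scale", "log2")
    kwargs.setdefault("batch", "B")
    return ca.ExpressionDataset(
        values=pd.DataFrame(values, index=features, columns=samples), **kwargs
    )


def make_merged(values, batches, features=None, samples=None, **kwargs):
    """Small MergedDataset straight from a matrix and per-sample batch labels."""
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=samples)
    return ca.MergedDataset(
        values=df, batch_of_sample=pd.Series(list(batches), index=samples), **kwargs
    )


def run_pipeline(datasets, maps, sample_info=None, target_bits=16, collapse="median"):
    prepared = []
    for ds, mapping in zip(datasets, maps):
        ds = ca.harmonize_dataset(ds, target_bits=target_bits)
        ds = ca.annotate_features(ds, mapping)
        ds = ca.collapse_features(ds, collapse)
        prepared.append(ds)
    return ca.intersect_and_merge(prepared, sample_info)


@pytest.fixture(scope="session")
def default_study():
    """The default 3-platform / 3-group simulated study, run once per session."""
    cfg = ca.SimulationConfig(seed=20240901)
    datasets, maps, info, truth = ca.simulate_study(cfg)
    merged = run_pipeline(datasets, maps, info)
    corrected = ca.remove_batch_effects(merged, "EB")
    return {
        "config": cfg,
        "datasets": datasets,
        "maps": maps,
        "sample_info": info,
        "truth": truth,
        "merged": merged,
        "corrected": corrected,
    }


@pytest.fixture(scope="session")
def default_metrics(default_study):
    return ca.evaluate_correction(
        default_study["merged"], default_study["corrected"], default_study["truth"]
    )


@pytest.fixture(scope="session")
def eb_recovery():
    """EB parameter-recovery harness: 2 batches x 20 samples, 2000 genes,
    gamma ~ N(0,1), delta2 ~ InvGamma(3,2), eps ~ N(0,1)."""
    values, batch, gamma, delta2 = ca.simulate_eb_model(
        n_genes=2000, n_batches=2, n_per_batch=20,
        sd_gamma=1.0, delta2_shape=3.0, delta2_scale=2.0, noise_sd=1.0, seed=1,
    )
    adjusted, params = ca.combat_eb(values, batch)
    return {
        "values": values,
        "batch": batch,
        "gamma": gamma,
        "delta2": delta2,
        "adjusted": adjusted,
        "params": params,
    }
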