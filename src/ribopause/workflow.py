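"""Config-driven orchestration and the injected-pause validation benchmark.

``run_pipeline`` executes the standard monosome path (read counts ->
TPM partition -> normalization -> EIF pause calls) from a YAML/dict config
and writes all artifacts, each stamped with the resolved-config hash.

``injected_pause_benchmark`` is the pipeline's self-validation: a seeded
synthetic translatome is generated, natural outliers are flattened and
ground-truth spikes injected, the full TPM-binned EIF pipeline scores every
codon, and recovery of the injected positions is summarized as ROC AUC plus
the TPR/FPR of the 0.95-quantile flag set.  ``replicate_codon_concordance``
checks that two replicate libraries sharing dwell-time ground truth yield
correlated per-codon pause-site fractions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import core, pauses, simulate

logger = logging.getLogger("ribopause")

DEFAULT_PARAMS = {
    "trees": 200,
    "quantile": 0.95,
    "bins": 5,
    "seed": 0,
    "min_mean_coverage": 0.0,
}

REQUIRED_KEYS = ("counts", "out_dir")


def _resolve_config(config: Mapping[str, Any]) -> dict[str, Any]:
    resolved = dict(config)
    for key in REQUIRED_KEYS:
        if key not in resolved:
            raise ValueError(f"config missing required key: {key!r}")
    params = dict(DEFAULT_PARAMS)
    params.update(resolved.get("params", {}))
    unknown = set(params) - set(DEFAULT_PARAMS)
    if unknown:
        raise ValueError(f"unknown pipeline parameters: {sorted(unknown)}")
    resolved["params"] = params
    return resolved


def _config_hash(resolved: Mapping[str, Any]) -> str:
    text = json.dumps(resolved, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def run_pipeline(config: Mapping[str, Any]) -> Path:
    """Counts TSV -> pause calls; returns the output directory."""
    resolved = _resolve_config(config)
    chash = _config_hash(resolved)
    params = resolved["params"]
    counts_path = Path(resolved["counts"])
    if not counts_path.exists():
        raise FileNotFoundError(f"counts file not found: {counts_path}")
    out = Path(resolved["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    profiles = core.read_counts_tsv(counts_path)
    tpm = core.compute_tpm(profiles)
    partition = core.partition_by_tpm(tpm, n_bins=params["bins"])
    normalized = core.normalize_profiles(
        profiles, min_mean_coverage=params["min_mean_coverage"]
    )
    calls = pauses.call_pauses(
        normalized, partition,
        n_trees=params["trees"],
        threshold_quantile=params["quantile"],
        seed=params["seed"],
    )

    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({**resolved, "config_hash": chash}, fh, sort_keys=True)
    partition.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
    pauses.write_calls_bed(calls, out / "calls.tsv")
    summary = {
        "config_hash": chash,
        "seed": params["seed"],
        "parameters": params,
        "n_orfs": len(profiles),
        "n_codons": int(len(calls)),
        "per_bin_pauses": {
            str(b): int(n)
            for b, n in calls[calls["is_pause"]].groupby("bin").size().items()
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Validation benchmarks
# ---------------------------------------------------------------------------

def injected_pause_benchmark(
    cfg: simulate.SimConfig | None = None,
    seed: int = 0,
    n_trees: int = 200,
    threshold_quantile: float = 0.95,
    psi_scale: float = 1.0,
) -> dict[str, float]:
    """One full simulate -> inject -> call -> ROC round trip.

    Returns ``auc``, ``tpr``, ``fpr`` (flag set = per-bin 0.95 score
    quantile), plus the problem size ``n_codons``.
    """
    if cfg is None:
        cfg = simulate.SimConfig(seed=seed)
    root = np.random.SeedSequence(cfg.seed)
    inject_seed, call_seed = (
        int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in root.spawn(2)
    )
    profiles, _, _ = simulate.generate_translatome(cfg)
    tpm = core.compute_tpm(profiles)
    partition = core.partition_by_tpm(tpm)
    normalized = core.normalize_profiles(profiles)
    injected, truth = simulate.inject_pauses(
        normalized, seed=inject_seed, pauses_per_orf=cfg.pauses_per_orf
    )
    calls = pauses.call_pauses(
        injected, partition,
        n_trees=n_trees, threshold_quantile=threshold_quantile,
        seed=call_seed, psi_scale=psi_scale,
    )
    labels = simulate.truth_labels(calls, truth)
    metrics = simulate.benchmark_roc(
        calls["score"].to_numpy(), labels, flags=calls["is_pause"].to_numpy()
    )
    metrics["n_codons"] = float(len(calls))
    return metrics


def mean_injected_benchmark(
    seeds: list[int], n_orfs: int = 2000, **kwargs
) -> dict[str, float]:
    """Average the injected-pause benchmark over several seeds."""
    runs = [
        injected_pause_benchmark(
            simulate.SimConfig(n_orfs=n_orfs, seed=s), **kwargs
        )
        for s in seeds
    ]
    return {
        k: float(np.mean([r[k] for r in runs])) for k in ("auc", "tpr", "fpr")
    } | {"n_codons": float(np.mean([r["n_codons"] for r in runs]))}


#: Slow-codon ground truth for the replicate-concordance benchmark: a
#: handful of proline/arginine/glycine codons with 3-5x dwell, the classic
#: pause-prone identities, on an otherwise uniform background.
REPLICATE_DWELL = {
    "CCG": 5.0, "CCA": 4.0, "AGG": 4.0, "CGA": 3.0, "GGG": 3.0,
}


def replicate_config(
    n_orfs: int = 2000, seed: int = 0, **kwargs
) -> simulate.SimConfig:
    """Study conditions for the two-replicate concordance benchmark."""
    return simulate.SimConfig(
        n_orfs=n_orfs, seed=seed, dwell=REPLICATE_DWELL, **kwargs
    )


def _pipeline_codon_fractions(
    profiles, sequences, seed: int, n_trees: int = 200
) -> dict[str, float]:
    tpm = core.compute_tpm(profiles)
    partition = core.partition_by_tpm(tpm)
    normalized = core.normalize_profiles(profiles)
    calls = pauses.call_pauses(normalized, partition, n_trees=n_trees, seed=seed)
    return pauses.pause_site_codon_fraction(calls, sequences, site="A")


def replicate_codon_concordance(
    cfg: simulate.SimConfig, n_trees: int = 200
) -> dict[str, float]:
    """Pearson r of per-codon A-site pause fractions across two replicates.

    The replicates share sequences and codon dwell multipliers and differ
    only in counting noise; each runs through the full pipeline
    independently.
    """
    reps, sequences, _ = simulate.generate_replicates(cfg, n_replicates=2)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    call_seeds = [
        int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in seeds[2:]
    ]
    f1 = _pipeline_codon_fractions(reps[0], sequences, call_seeds[0], n_trees)
    f2 = _pipeline_codon_fractions(reps[1], sequences, call_seeds[1], n_trees)
    r = pauses.replicate_concordance(f1, f2)
    return {"pearson_r": float(r), "n_codons_compared": 61.0}


def run_benchmark(
    seed: int = 0,
    n_orfs: int = 500,
    trees_grid: tuple[int, ...] = (50, 100, 200, 400),
    psi_grid: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> dict[str, Any]:
    """Hyperparameter-robustness sweep of the injected-pause benchmark."""
    cfg = simulate.SimConfig(n_orfs=n_orfs, seed=seed)
    sweep_trees = {
        str(t): injected_pause_benchmark(cfg, n_trees=t) for t in trees_grid
    }
    sweep_psi = {
        str(s): injected_pause_benchmark(cfg, psi_scale=s) for s in psi_grid
    }
    return {"trees": sweep_trees, "psi_scale": sweep_psi}
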