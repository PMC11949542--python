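"""End-to-end orchestration: data -> embedding -> metrics -> interpretation.

A :class:`RunConfig` (loadable from a YAML file; CLI flags override file
values) drives the study pipeline on synthetic or user-supplied networks:

1. load networks from disk, or simulate microconnectome-like networks;
2. train the autoencoder at a fixed (depth, middle size) with a seeded
   train/validation split (or run the architecture survey);
3. extract per-node features for every network;
4. compute the 15-metric table per network;
5. interpret features against metrics (MI, permutation p, BH q,
   min-max normalisation, best-metric category proportions);
6. evaluate swap degradation in both modes;
7. run the PCA baseline at matched component count.

Every file written during a run is listed in ``manifest.yaml`` together
with the parameters and seeds that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import baseline, interpret, metrics, nne, robustness, synthgen
from .exceptions import ConfigurationError
from .netio import DirectedBinaryNetwork, make_folds, read_network, transpose_network

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with per-stage seeds."""

    # data
    network_paths: list[str] = field(default_factory=list)
    network_format: str = "dense"
    simulate: bool = True
    n_networks: int = 14
    n_nodes: int = 100
    density: float = 0.1
    heavy_tail_exponent: float = 2.2
    reciprocity: float = 0.3
    transposed: bool = False
    # architecture / training
    depth: int = 3
    middle_size: int = 13
    patience: int = 50
    max_epochs: int = 2000
    batch_size: int = 32
    n_folds: int = 0  # 0 -> single seeded train/val split, no survey
    # metrics / interpretation
    hub_fraction: float = 0.2
    degree_kind: str = "out"
    direction: str = "forward"
    mi_neighbors: int = 3
    n_permutations: int = 100
    # robustness
    swap_fractions: list[float] = field(
        default_factory=lambda: [float(f) for f in synthgen.DEFAULT_SWAP_FRACTIONS]
    )
    swap_replicates: int = 5
    # global
    seed: int = 0
    out_dir: str = "nne_run"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_networks(config: RunConfig) -> list[DirectedBinaryNetwork]:
    if config.network_paths:
        nets = [
            read_network(p, fmt=config.network_format) for p in config.network_paths
        ]
    elif config.simulate:
        nets = [
            synthgen.generate_microconnectome_like(
                config.n_nodes,
                config.density,
                config.heavy_tail_exponent,
                config.reciprocity,
                seed=config.seed + i,
            )
            for i in range(config.n_networks)
        ]
    else:
        raise ConfigurationError("no network paths given and simulation disabled")
    if config.transposed:
        nets = [transpose_network(n) for n in nets]
    return nets


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "files": [], "stages": {}}

    def record(path: Path, stage: str):
        manifest["files"].append(str(path.relative_to(out)))
        manifest["stages"].setdefault(stage, []).append(str(path.relative_to(out)))

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", stage)
                return self

            def __exit__(self, *exc):
                logger.info(
                    "stage %s finished in %.1fs", stage, time.perf_counter() - self.t0
                )

        return _T()

    with timed("data"):
        nets = _load_networks(config)
        for net in nets:
            path = out / f"network_{net.name}.tsv"
            np.savetxt(path, net.adjacency, fmt="%d", delimiter="\t")
            record(path, "data")

    tcfg = nne.TrainingConfig(
        patience=config.patience,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    arch = nne.NNEArchitecture(nets[0].n_nodes, config.depth, config.middle_size)

    with timed("train"):
        if config.n_folds:
            survey = nne.grid_survey(
                nets, [config.depth], [config.middle_size], tcfg,
                n_folds=config.n_folds, seed=config.seed,
            )
            path = out / "survey.tsv"
            survey.to_csv(path, sep="\t", index=False)
            record(path, "train")
        # refit on everything: seeded split of validation networks
        folds = make_folds(
            nets, n_folds=len(nets), n_validation=max(1, len(nets) // 5),
            seed=config.seed,
        )
        val_idx = folds.validation_of[0]
        train_idx = [i for i in range(len(nets)) if i not in val_idx]
        model = nne.train(
            [nets[i] for i in train_idx], [nets[i] for i in val_idx], arch, tcfg
        )
        path = out / "training_history.tsv"
        model.history.to_csv(path, sep="\t", index=False)
        record(path, "train")
        path = out / "architecture.txt"
        path.write_text(
            f"input_size={arch.input_size}\ndepth={arch.depth}\n"
            f"middle_size={arch.middle_size}\n"
            f"layer_sizes={','.join(map(str, arch.layer_sizes))}\n"
            f"stopped_epoch={model.stopped_epoch}\n"
        )
        record(path, "train")

    with timed("features"):
        feature_mats = []
        for net in nets:
            fm = nne.extract_features(model, net)
            feature_mats.append(fm)
            path = out / f"features_{net.name}.tsv"
            fm.to_frame().to_csv(path, sep="\t")
            record(path, "features")

    with timed("metrics"):
        tables = []
        for net in nets:
            table = metrics.compute_all_metrics(
                net,
                hub_fraction=config.hub_fraction,
                degree_kind=config.degree_kind,
                direction=config.direction,
                seed=config.seed,
            )
            tables.append(table)
            path = out / f"metrics_{net.name}.tsv"
            table.values.to_csv(path, sep="\t")
            record(path, "metrics")

    with timed("interpret"):
        results = []
        for i, (fm, table) in enumerate(zip(feature_mats, tables)):
            res = interpret.interpret_features(
                fm, table,
                k=config.mi_neighbors,
                n_perm=config.n_permutations or None,
                seed=config.seed + i,
            )
            results.append(res)
            for label, frame in (
                ("mi", res.mi), ("mi_normalized", res.mi_normalized),
                ("p", res.p_values), ("q", res.q_values),
            ):
                if frame is None:
                    continue
                path = out / f"interpret_{label}_{nets[i].name}.tsv"
                frame.to_csv(path, sep="\t")
                record(path, "interpret")
        proportions = interpret.aggregate_proportions(results)
        path = out / "category_proportions.tsv"
        with open(path, "w") as fh:
            fh.write("category\tproportion\n")
            for c, v in proportions.items():
                fh.write(f"{c}\t{v:.6f}\n")
        record(path, "interpret")

    with timed("robustness"):
        curves = {}
        for preserve in (True, False):
            curve = robustness.evaluate_swapped(
                model, nets, config.swap_fractions,
                preserve_degree=preserve,
                n_reps=config.swap_replicates,
                seed=config.seed,
            )
            curves[preserve] = curve
            path = out / f"degradation_{curve.mode}.tsv"
            curve.to_frame().to_csv(path, sep="\t", index=False)
            record(path, "robustness")
        gap = robustness.compare_modes(curves[True], curves[False])
        path = out / "mode_comparison.txt"
        path.write_text(
            f"tp_auc_gap={gap['tp_auc_gap']:.6f}\n"
            f"loss_auc_gap={gap['loss_auc_gap']:.6f}\n"
        )
        record(path, "robustness")

    with timed("baseline"):
        _, pca_report = baseline.pca_reconstruct(nets, config.middle_size)
        import pandas as pd

        nne_rows = []
        for net in nets:
            recon, _ = nne.reconstruct(model, net)
            nne_rows.append(
                {
                    "network": net.name,
                    "accuracy": nne.accuracy(recon.adjacency, net.adjacency),
                    "error_rate": nne.error_rate(recon.adjacency, net.adjacency),
                    "tp_accuracy": nne.tp_accuracy(recon.adjacency, net.adjacency),
                }
            )
        nne_report = baseline.BaselineReport(
            "nne", config.middle_size, pd.DataFrame(nne_rows)
        )
        comparison = baseline.compare_nne_pca(nne_report, pca_report)
        for label, frame in (
            ("nne", nne_report.table), ("pca", pca_report.table),
        ):
            path = out / f"baseline_{label}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            record(path, "baseline")
        path = out / "baseline_comparison.tsv"
        comparison.to_csv(path, sep="\t")
        record(path, "baseline")

    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    logger.info("run complete: %s (%d files)", out, len(manifest["files"]))
    return out
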