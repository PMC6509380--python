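"""End-to-end orchestration and the command-line interface.

``run_all`` wires the stages together: simulate (or load) posterior topology
pools per barcode × backbone condition, select the analysis trees (top-k by
symmetric distance to the family backbone, or a random k for
backbone-constrained runs), smooth them to ultrametric relative-time trees,
evaluate the diversity metrics per plot, and run the 24-model mixed-effects
comparison with the bootstrap robustness check for every metric.  Outputs
are plain CSV/Newick files plus a JSON run manifest.

The CLI exposes each stage as a subcommand (``simulate``, ``rank``,
``ultrametricize``, ``metrics``, ``fit``) plus ``run-all``.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronos import make_ultrametric
from .conditions import Condition, enumerate_conditions
from .metrics import ALL_METRICS, CommunityMatrix, compute_diversity_table
from .models import DiversityModelSet
from .synth import SynthConfig, simulate_dataset
from .trees import (
    TopologySet, clade_support, parse_newick, rank_and_select,
    random_select, read_family_map, write_newick,
)

__all__ = ["RunConfig", "run_all", "main"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults follow the emulated study design: the 500 top-ranked
    topologies per condition, smoothing penalty λ = 1000, and 100 bootstrap
    replicates.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    top_k: int = 500
    smoothing_lambda: float = 1000.0
    ultrametricize: bool = True
    metrics: tuple = ALL_METRICS
    bootstrap: int = 100
    seed: int = 0
    outdir: str = "phylodiv_out"
    # optional pre-existing inputs (paths); when set, synthesis is skipped
    tree_files: dict | None = None        # condition label -> newick path
    backbone_file: str | None = None
    community_file: str | None = None
    family_map_file: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig.from_dict(d["synth"])
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "synth": self.synth.to_dict(),
            "top_k": self.top_k,
            "smoothing_lambda": self.smoothing_lambda,
            "ultrametricize": self.ultrametricize,
            "metrics": list(self.metrics),
            "bootstrap": self.bootstrap,
            "seed": self.seed,
            "outdir": self.outdir,
            "tree_files": self.tree_files,
            "backbone_file": self.backbone_file,
            "community_file": self.community_file,
            "family_map_file": self.family_map_file,
        }


def _split_str(split) -> str:
    a, b = sorted((sorted(side) for side in split))
    return " ".join(a) + " | " + " ".join(b)


def _stage(name):
    logger.info("stage: %s", name)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory outputs and writes
    CSV/Newick/JSON artifacts under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    _stage("inputs")
    if cfg.tree_files:
        pools = []
        for label, path in cfg.tree_files.items():
            cond = Condition.from_label(label)
            pools.append(TopologySet(parse_newick(Path(path)), condition=cond))
        backbone = parse_newick(Path(cfg.backbone_file))[0]
        community = CommunityMatrix.from_csv(cfg.community_file)
        family_map = (
            read_family_map(cfg.family_map_file)
            if cfg.family_map_file else None
        )
    else:
        synth_cfg = cfg.synth
        if synth_cfg.seed != cfg.seed:
            synth_cfg = SynthConfig.from_dict(
                {**synth_cfg.to_dict(), "seed": cfg.seed}
            )
        data = simulate_dataset(synth_cfg)
        pools = data.sets
        backbone = data.backbone
        community = data.community
        family_map = data.family_map
        write_newick(data.truth, out / "truth.nwk")
        write_newick(backbone, out / "backbone.nwk")
        community.to_csv(out / "community.csv")
        pd.DataFrame(
            sorted(family_map.items()), columns=["species", "family"]
        ).to_csv(out / "family_map.csv", index=False)

    _stage("topology selection")
    ss = np.random.SeedSequence(cfg.seed).spawn(len(pools) + len(cfg.metrics))
    selected = []
    rf_rows = []
    for i, pool in enumerate(pools):
        cond = pool.condition
        try:
            if cond.has_backbone:
                sel = random_select(
                    pool.trees, cfg.top_k,
                    seed=np.random.default_rng(ss[i]), condition=cond,
                )
            else:
                sel = rank_and_select(
                    pool.trees, backbone, cfg.top_k,
                    family_map=family_map, condition=cond,
                )
                for j, d in enumerate(sel.rf_backbone):
                    rf_rows.append((cond.label, j, d))
        except Exception as exc:
            raise RuntimeError(
                f"selection failed for condition {cond}: {exc}"
            ) from exc
        selected.append(sel)
    if rf_rows:
        pd.DataFrame(
            rf_rows, columns=["condition", "tree_index", "rf_to_backbone"]
        ).to_csv(out / "rf_to_backbone.csv", index=False)

    if cfg.ultrametricize:
        _stage("rate smoothing")
        smoothed = []
        for sel in selected:
            try:
                trees = [
                    make_ultrametric(t, cfg.smoothing_lambda)
                    for t in sel.trees
                ]
            except Exception as exc:
                raise RuntimeError(
                    f"smoothing failed for condition {sel.condition}: {exc}"
                ) from exc
            smoothed.append(TopologySet(
                trees, condition=sel.condition, rf_backbone=sel.rf_backbone
            ))
        selected = smoothed

    for sel in selected:
        write_newick(sel.trees, out / f"trees_{sel.condition.label}.nwk")

    _stage("clade support")
    sup_rows = []
    for sel in selected:
        for split, freq in sorted(
            clade_support(sel).items(), key=lambda kv: -kv[1]
        ):
            sup_rows.append((sel.condition.label, _split_str(split), freq))
    pd.DataFrame(
        sup_rows, columns=["condition", "split", "support"]
    ).to_csv(out / "clade_support.csv", index=False)

    _stage("diversity metrics")
    table = compute_diversity_table(selected, community, cfg.metrics)
    table.to_csv(out / "diversity.csv", index=False)

    _stage("model comparison")
    results = {}
    for j, metric in enumerate(cfg.metrics):
        res = DiversityModelSet(table, metric=metric).fit(
            n_boot=cfg.bootstrap,
            seed=np.random.default_rng(ss[len(pools) + j]),
        )
        slug = metric.lower()
        res.model_table.to_csv(
            out / f"model_comparison_{slug}.csv", index=False
        )
        res.averaged_coefs.to_csv(
            out / f"averaged_coefs_{slug}.csv", index=False
        )
        results[metric] = res

    manifest = {
        "package": "phylodiv",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_conditions": len(selected),
        "trees_per_condition": len(selected[0]),
        "runtime_s": round(time.time() - t0, 2),
        "outputs": sorted(
            {p.name for p in out.iterdir()} | {"manifest.json"}
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "selected": selected, "community": community, "backbone": backbone,
        "diversity": table, "results": results, "manifest": manifest,
    }


# -- CLI -------------------------------------------------------------------


def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="phylodiv",
        description="Barcode/backbone sensitivity of community phylogenetic "
                    "diversity estimates",
    )
    p.add_argument("--version", action="version",
                   version=f"phylodiv {__version__}")
    sub = p.add_subparsers(dest="command")

    sp = sub.add_parser("simulate", help="generate a synthetic study")
    sp.add_argument("--config", help="YAML run/synth config")
    sp.add_argument("--seed", type=int, default=0)
    sp.add_argument("--out", required=True)

    rp = sub.add_parser("rank", help="rank topologies against a backbone")
    rp.add_argument("--trees", required=True)
    rp.add_argument("--backbone", required=True)
    rp.add_argument("--family-map")
    rp.add_argument("--topk", type=int, required=True)
    rp.add_argument("--out", required=True)

    up = sub.add_parser("ultrametricize", help="penalized rate smoothing")
    up.add_argument("--trees", required=True)
    up.add_argument("--lambda", dest="lam", type=float, default=1000.0)
    up.add_argument("--out", required=True)

    mp = sub.add_parser("metrics", help="per-plot diversity metrics")
    mp.add_argument("--trees", required=True)
    mp.add_argument("--condition", required=True,
                    help="condition label, e.g. R+M+I+B")
    mp.add_argument("--community", required=True)
    mp.add_argument("--metrics", nargs="+", default=list(ALL_METRICS))
    mp.add_argument("--out", required=True)

    fp = sub.add_parser("fit", help="24-model mixed-effects comparison")
    fp.add_argument("--diversity", required=True)
    fp.add_argument("--metric", required=True)
    fp.add_argument("--bootstrap", type=int, default=100)
    fp.add_argument("--seed", type=int, default=0)
    fp.add_argument("--out", required=True)

    ap = sub.add_parser("run-all", help="full pipeline")
    ap.add_argument("--config", help="YAML RunConfig")
    ap.add_argument("--seed", type=int)
    ap.add_argument("--out")
    ap.add_argument("--topk", type=int)
    ap.add_argument("--lambda", dest="lam", type=float)
    ap.add_argument("--metrics", nargs="+")
    ap.add_argument("--bootstrap", type=int)
    return p


def main(argv=None) -> int:
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    parser = _build_parser()
    args = parser.parse_args(argv)
    if args.command is None:
        parser.print_usage(sys.stderr)
        return 2
    try:
        if args.command == "simulate":
            cfg = (RunConfig.from_yaml(args.config).synth
                   if args.config else SynthConfig())
            cfg = SynthConfig.from_dict({**cfg.to_dict(), "seed": args.seed})
            data = simulate_dataset(cfg)
            out = Path(args.out)
            out.mkdir(parents=True, exist_ok=True)
            write_newick(data.truth, out / "truth.nwk")
            write_newick(data.backbone, out / "backbone.nwk")
            data.community.to_csv(out / "community.csv")
            pd.DataFrame(
                sorted(data.family_map.items()),
                columns=["species", "family"],
            ).to_csv(out / "family_map.csv", index=False)
            for ts in data.sets:
                write_newick(
                    ts.trees, out / f"pool_{ts.condition.label}.nwk"
                )
            print(f"wrote synthetic study to {out}")
        elif args.command == "rank":
            trees = parse_newick(Path(args.trees))
            backbone = parse_newick(Path(args.backbone))[0]
            fmap = read_family_map(args.family_map) if args.family_map else None
            sel = rank_and_select(trees, backbone, args.topk, family_map=fmap)
            write_newick(sel.trees, args.out)
            pd.DataFrame({
                "tree_index": range(len(sel)),
                "rf_to_backbone": sel.rf_backbone,
            }).to_csv(Path(args.out).with_suffix(".csv"), index=False)
            print(f"kept {len(sel)} trees -> {args.out}")
        elif args.command == "ultrametricize":
            trees = parse_newick(Path(args.trees))
            write_newick(
                [make_ultrametric(t, args.lam) for t in trees], args.out
            )
            print(f"smoothed {len(trees)} trees -> {args.out}")
        elif args.command == "metrics":
            ts = TopologySet(
                parse_newick(Path(args.trees)),
                condition=Condition.from_label(args.condition),
            )
            cm = CommunityMatrix.from_csv(args.community)
            compute_diversity_table([ts], cm, tuple(args.metrics)).to_csv(
                args.out, index=False
            )
            print(f"wrote diversity table -> {args.out}")
        elif args.command == "fit":
            table = pd.read_csv(args.diversity)
            res = DiversityModelSet(table, metric=args.metric).fit(
                n_boot=args.bootstrap, seed=args.seed
            )
            out = Path(args.out)
            out.mkdir(parents=True, exist_ok=True)
            slug = args.metric.lower()
            res.model_table.to_csv(
                out / f"model_comparison_{slug}.csv", index=False
            )
            res.averaged_coefs.to_csv(
                out / f"averaged_coefs_{slug}.csv", index=False
            )
            print(res.summary())
        elif args.command == "run-all":
            cfg = (RunConfig.from_yaml(args.config)
                   if args.config else RunConfig())
            d = cfg.to_dict()
            if args.seed is not None:
                d["seed"] = args.seed
            if args.out:
                d["outdir"] = args.out
            if args.topk:
                d["top_k"] = args.topk
            if args.lam:
                d["smoothing_lambda"] = args.lam
            if args.metrics:
                d["metrics"] = args.metrics
            if args.bootstrap is not None:
                d["bootstrap"] = args.bootstrap
            cfg = RunConfig.from_dict(d)
            outputs = run_all(cfg)
            for metric, res in outputs["results"].items():
                print(res.summary())
                print()
        return 0
    except FileNotFoundError as exc:
        print(f"error: file not found: {exc.filename or exc}", file=sys.stderr)
        return 1
    except Exception as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1


if __name__ == "__main__":
    raise SystemExit(main())
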