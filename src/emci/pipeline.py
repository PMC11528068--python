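"""End-to-end orchestration: preprocess -> correlate -> image -> train ->
attribute -> deconvolve -> evaluate -> colocalize, from a single config.

Every stage writes its outputs under the run directory and records a SHA-256
hash per output file in ``manifest.json`` together with parameters, seeds and
summary statistics. Stage outputs are pure functions of (inputs, config,
seed), so reruns with the same config produce identical hashes; a rerun into
an existing run directory reuses a stage's outputs when its recorded config
hash and file hashes still verify.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from emci import (
    attribution,
    classifier,
    communication,
    correlation,
    deconvolution,
    evaluation,
    imaging,
    preprocess,
    synthetic,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """Parameters for one full run. Either ``inputs`` (paths to sc/st/coords/
    labels and optionally truth) or ``simulate`` (SyntheticConfig fields) must
    be provided."""

    output_dir: str
    inputs: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    raster_size: int | str = "auto"  # "auto" shrinks to an integer spot grid
    cell_frac: float = 0.05
    spot_frac: float = 0.01
    classifier: dict[str, Any] = field(default_factory=dict)
    train_frac: float = 0.7
    attribution: dict[str, Any] = field(default_factory=dict)
    fuse_mode: str = "minmax"
    top_frac: float = 0.2

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' must be given")
        # every stochastic stage needs an explicit seed before anything runs
        if self.simulate is not None and "seed" not in self.simulate:
            raise ValueError("simulate config must declare a seed")
        if "seed" not in self.classifier:
            raise ValueError("classifier config must declare a seed")
        if "seed" not in self.attribution:
            raise ValueError("attribution config must declare a seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, cfg: RunConfig):
        self.path = outdir / "manifest.json"
        self.data: dict[str, Any] = {
            "config_hash": cfg.config_hash(),
            "stages": {},
            "summary": {},
        }
        self.prev: dict[str, Any] = {}
        if self.path.exists():
            try:
                prev = json.loads(self.path.read_text())
                if prev.get("config_hash") == self.data["config_hash"]:
                    self.prev = prev.get("stages", {})
            except (json.JSONDecodeError, OSError):
                pass

    def cached(self, stage: str) -> bool:
        entry = self.prev.get(stage)
        if not entry:
            return False
        for f, digest in entry.get("outputs", {}).items():
            p = Path(f)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], seconds: float,
               cached: bool = False, **extra: Any) -> None:
        self.data["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "wall_seconds": round(seconds, 3),
            "cached": cached,
            **extra,
        }

    def fail(self, stage: str, err: Exception) -> None:
        self.data["stages"][stage] = {"failed": True, "error": f"{type(err).__name__}: {err}"}
        self.write()

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_end_to_end(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the manifest dictionary.

    Any stage failure is recorded in the manifest and re-raised.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
    manifest = _Manifest(outdir, cfg)
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        truth_df = None
        if cfg.simulate is not None:
            sim_cfg = synthetic.SyntheticConfig(**cfg.simulate)
            fixture_dir = outdir / "fixture"
            paths = synthetic.write_fixture(sim_cfg, fixture_dir)
            truth_df = pd.read_csv(paths["truth"], index_col=0)
            manifest.record(stage, list(paths.values()), time.perf_counter() - t0,
                            seed=sim_cfg.seed)
            input_paths = {k: str(paths[k]) for k in ("sc", "st", "coords", "labels")}
        else:
            input_paths = dict(cfg.inputs)
            truth_path = input_paths.pop("truth", None)
            if truth_path:
                truth_df = pd.read_csv(truth_path, index_col=0)

        stage = "preprocess"
        t0 = time.perf_counter()
        sc, st = preprocess.load_paired_dataset(
            input_paths["sc"], input_paths["st"],
            input_paths["coords"], input_paths["labels"],
        )
        sc, st = preprocess.filter_and_align(sc, st, cfg.cell_frac, cfg.spot_frac)
        pre_dir = outdir / "preprocessed"
        pre_paths = preprocess.save_paired_dataset(sc, st, pre_dir)
        manifest.record(stage, list(pre_paths.values()), time.perf_counter() - t0,
                        n_cells=sc.n_cells, n_spots=st.n_spots, n_genes=sc.n_genes)

        stage = "correlate"
        t0 = time.perf_counter()
        tensor_dir = outdir / "tensor"
        if manifest.cached(stage):
            tensor = correlation.CorrelationTensor.load(tensor_dir)
            manifest.record(stage, [tensor_dir / f"W_{n}.csv" for n in tensor.metric_names]
                            + [tensor_dir / "tensor.json"],
                            time.perf_counter() - t0, cached=True)
        else:
            tensor = correlation.build_tensor(sc, st)
            tensor.save(tensor_dir)
            manifest.record(stage, sorted(tensor_dir.iterdir()), time.perf_counter() - t0)

        stage = "image"
        t0 = time.perf_counter()
        coords = st.coords_frame()
        if cfg.raster_size == "auto":
            H, W = imaging.choose_raster(coords)
        else:
            H = W = int(cfg.raster_size)
        pmap = imaging.build_pixel_map(coords, H, W)
        images = imaging.render_all(tensor, pmap)
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        pmap.save(img_dir / "pixel_map.tsv")
        np.save(img_dir / "pseudo_images.npy", images)
        manifest.record(stage, [img_dir / "pixel_map.tsv", img_dir / "pseudo_images.npy"],
                        time.perf_counter() - t0, raster=[H, W],
                        n_pixels=pmap.n_pixels)

        stage = "train"
        t0 = time.perf_counter()
        clf_cfg = classifier.ClassifierConfig(**cfg.classifier)
        label_cols = list(sc.labels.columns[: clf_cfg.heads])
        clf = classifier.train(
            images, sc.labels[label_cols], clf_cfg,
            cell_ids=sc.cell_ids, train_frac=cfg.train_frac,
        )
        model_path = outdir / "model.npz"
        clf.save(model_path)
        clf.history.to_csv(outdir / "history.tsv", sep="\t", index=False)
        manifest.record(
            stage, [model_path, model_path.with_suffix(".json"), outdir / "history.tsv"],
            time.perf_counter() - t0, seed=clf_cfg.seed,
            test_accuracy=clf.test_accuracy, weights_hash=clf.weights_hash(),
        )
        manifest.data["summary"]["test_accuracy"] = clf.test_accuracy

        stage = "attribute"
        t0 = time.perf_counter()
        att_cfg = dict(cfg.attribution)
        att_seed = int(att_cfg.get("seed", 0))
        n_samples = int(att_cfg.get("n_samples", 500))
        cells_per_type = int(att_cfg.get("cells_per_type", 20))
        K = int(att_cfg.get("K", min(40, pmap.n_pixels)))
        seg = attribution.segment_superpixels(pmap, K=K)
        cell_types = sc.labels["cell_type"].astype(str)
        rng = np.random.default_rng(att_seed)
        maps = []
        for t in sorted(cell_types.unique()):
            ids = np.array(cell_types.index[cell_types == t], dtype=object)
            take = ids[rng.permutation(len(ids))[:cells_per_type]]
            for cid in take:
                i = sc.cell_ids.index(str(cid))
                img = imaging.PseudoImage(images[i], str(cid), pmap.mask())
                maps.append(
                    attribution.explain(clf, img, seg, target=t,
                                        n_samples=n_samples, seed=att_seed)
                )
        type_maps = attribution.aggregate_by_type(maps, cell_types)
        att_dir = outdir / "attribution"
        att_dir.mkdir(exist_ok=True)
        att_files = []
        for t, amap in type_maps.items():
            p = att_dir / f"attribution_{t}.csv"
            pd.DataFrame(amap.values).to_csv(p, index=False)
            att_files.append(p)
            sp = att_dir / f"spots_{t}.tsv"
            amap.spot_values(pmap).rename_axis("spot_id").to_csv(sp, sep="\t")
            att_files.append(sp)
        manifest.record(stage, att_files, time.perf_counter() - t0,
                        seed=att_seed, K=seg.K, n_samples=n_samples,
                        cells_per_type=cells_per_type)

        stage = "deconvolve"
        t0 = time.perf_counter()
        profiles = deconvolution.fuse_and_profile(tensor, cell_types, cfg.fuse_mode)
        props = deconvolution.proportions(profiles, cfg.fuse_mode)
        dec_dir = outdir / "deconvolution"
        dec_dir.mkdir(exist_ok=True)
        props.values.rename_axis("spot_id").to_csv(dec_dir / "proportions.csv")
        props.predominant_type().rename("predominant_type").rename_axis("spot_id").to_csv(
            dec_dir / "predominant.tsv", sep="\t"
        )
        row_sums = props.values.to_numpy(float).sum(axis=1)
        manifest.record(stage, [dec_dir / "proportions.csv", dec_dir / "predominant.tsv"],
                        time.perf_counter() - t0, fuse_mode=cfg.fuse_mode)
        manifest.data["summary"]["simplex_max_row_error"] = float(
            np.abs(row_sums - 1.0).max()
        )

        stage = "evaluate"
        if truth_df is not None:
            t0 = time.perf_counter()
            report = evaluation.evaluate_proportions(props.values, truth_df)
            report.to_csv(dec_dir / "metrics.csv")
            regions = truth_df.idxmax(axis=1).astype(str)
            shared = [s for s in props.values.index if s in regions.index]
            ari_val = deconvolution.ari(
                props.predominant_type().loc[shared], regions.loc[shared]
            )
            manifest.record(stage, [dec_dir / "metrics.csv"], time.perf_counter() - t0)
            manifest.data["summary"]["per_type_pcc"] = report["PCC"].to_dict()
            manifest.data["summary"]["min_per_type_pcc"] = float(report["PCC"].min())
            manifest.data["summary"]["ari"] = ari_val

        stage = "colocalize"
        t0 = time.perf_counter()
        icc = communication.icc_matrix(type_maps, pmap)
        icc_dir = outdir / "icc"
        icc_dir.mkdir(exist_ok=True)
        icc_files = []
        for name, df in [("icc", icc.values), ("mi", icc.mi), ("sc", icc.sc),
                         ("pcc", icc.pcc)]:
            p = icc_dir / f"{name}.csv"
            df.to_csv(p)
            icc_files.append(p)
        manifest.record(stage, icc_files, time.perf_counter() - t0)
        manifest.data["summary"]["icc_path"] = str(icc_dir / "icc.csv")

    except Exception as err:  # record the failing stage, then propagate
        manifest.fail(stage, err)
        raise

    manifest.write()
    return manifest.data
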