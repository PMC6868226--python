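"""End-to-end grading pipeline and model persistence.

The jointly multi-modal pipeline (JMBoF) runs, in order: spatial L*a*b*
color-patch extraction, SURF detection/description, per-modality k-means
dictionaries fit on the training split, visual-word histogram encoding,
concatenation (color first), low-rank + sparse decomposition of the
training descriptor matrix with projection of all descriptors onto the
recovered basis, and finally a grid-searched RBF SVM.  Single-modality
baselines (RGB / HSI / L*a*b* color patches, or SURF alone, each + BoF +
SVM, no low-rank step) run on the identical split for comparison.

All randomness flows from the one configured seed, from which per-stage
seeds are derived; a run manifest records the configuration, seeds,
per-stage timings, dictionary sizes, recovered rank/residual, split
counts and the metric summary.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass

import joblib
import numpy as np

from . import bof, classify, color, evaluate, lowrank, surf
from .io import SeedImage, load_dataset_dir
from .synth import SynthConfig, generate_dataset

__all__ = [
    "PipelineConfig",
    "PipelineModel",
    "ModelReport",
    "PipelineResult",
    "run_pipeline",
    "save_model",
    "load_model",
    "ModelIOError",
]

MODEL_FORMAT_VERSION = 1

BASELINES = ("rgb", "hsi", "lab", "surf")


class ModelIOError(RuntimeError):
    """Raised when a persisted model cannot be read back."""


@dataclass
class PipelineConfig:
    """Configuration of one full grading experiment."""

    data_dir: str | None = None  # directory of grade-labeled images, or
    synth: SynthConfig | None = None  # generate the dataset instead
    dict_size_color: int = 800
    dict_size_surf: int = 800
    tile: int = 16
    hessian_threshold: float = surf.DEFAULT_THRESHOLD
    surf_octaves: int = 3
    surf_levels: int = 4
    lam: float | None = None  # None -> lam_scale / sqrt(max(d, n))
    lam_scale: float = 4.0
    energy: float = 0.99
    transductive: bool = True
    train_fraction: float = 0.7
    svm: classify.SvmConfig | None = None
    baselines: tuple = BASELINES
    linearize_rgb: bool = False
    seed: int = 0


@dataclass
class ModelReport:
    """Train/test evaluation of one model (JMBoF or a baseline)."""

    name: str
    train: evaluate.PRReport
    test: evaluate.PRReport

    def summary(self) -> dict:
        return {
            "model": self.name,
            "train_accuracy_percent": evaluate.round_half_up(
                self.train.accuracy_percent
            ),
            "train_map": round(self.train.map_score, 3),
            "test_accuracy_percent": evaluate.round_half_up(
                self.test.accuracy_percent
            ),
            "test_map": round(self.test.map_score, 3),
        }


@dataclass
class PipelineModel:
    """Everything needed to grade new images with a fitted JMBoF model."""

    color_dict: bof.VisualDictionary
    surf_dict: bof.VisualDictionary
    lowrank_model: lowrank.LowRankModel
    classifier: classify.ClassifierModel
    config: PipelineConfig

    def describe(self, image: SeedImage) -> np.ndarray:
        """Joint color+SURF visual-word histogram of one image."""
        lab = color.rgb_to_lab(image.pixels, linearize=self.config.linearize_rgb)
        cfeat = color.extract_color_patch_features(lab, tile=self.config.tile)
        _, sfeat = surf.extract_surf(
            image.pixels,
            hessian_threshold=self.config.hessian_threshold,
            octaves=self.config.surf_octaves,
            levels=self.config.surf_levels,
        )
        ch = bof.encode_histogram(cfeat, self.color_dict)
        if sfeat.shape[0]:
            sh = bof.encode_histogram(sfeat, self.surf_dict)
        else:
            sh = bof.BofHistogram("surf", np.zeros(self.surf_dict.k))
        return bof.join_descriptors(ch, sh)

    def predict(self, images: list[SeedImage]) -> tuple[np.ndarray, np.ndarray]:
        """Grade labels and per-class decision scores for raw images."""
        joint = np.column_stack([self.describe(im) for im in images])
        reduced = lowrank.project_descriptors(self.lowrank_model, joint).T
        return classify.predict(self.classifier, reduced)


@dataclass
class PipelineResult:
    reports: dict  # model name -> ModelReport ("jmbof" + baselines)
    model: PipelineModel
    manifest: dict


def _extract_all(images, cfg, need, log):
    """Per-image raw local features for every needed modality."""
    feats = {m: [] for m in need}
    t0 = time.perf_counter()
    for im in images:
        if "lab" in need:
            lab = color.rgb_to_lab(im.pixels, linearize=cfg.linearize_rgb)
            feats["lab"].append(
                color.extract_color_patch_features(lab, tile=cfg.tile)
            )
        if "rgb" in need:
            feats["rgb"].append(
                color.extract_color_patch_features(im.pixels, tile=cfg.tile)
            )
        if "hsi" in need:
            feats["hsi"].append(
                color.extract_color_patch_features(
                    color.rgb_to_hsi(im.pixels), tile=cfg.tile
                )
            )
        if "surf" in need:
            _, d = surf.extract_surf(
                im.pixels,
                hessian_threshold=cfg.hessian_threshold,
                octaves=cfg.surf_octaves,
                levels=cfg.surf_levels,
            )
            feats["surf"].append(d)
    log["extract_seconds"] = round(time.perf_counter() - t0, 3)
    return feats


def _encode_all(feats, dictionary):
    hists = []
    for f in feats:
        if f.shape[0] == 0:
            hists.append(bof.BofHistogram(dictionary.modality, np.zeros(dictionary.k)))
        else:
            hists.append(bof.encode_histogram(f, dictionary))
    return np.stack([h.counts for h in hists])  # (n, k)


def _evaluate_model(name, model, X_train, y_train, X_test, y_test) -> ModelReport:
    classes = tuple(model.classes)
    rep = {}
    for split, X, y in (("train", X_train, y_train), ("test", X_test, y_test)):
        labels, scores = classify.predict(model, X)
        rep[split] = evaluate.pr_report(y, labels, scores, classes=classes)
    return ModelReport(name=name, train=rep["train"], test=rep["test"])


def default_experiment_config(
    seed: int = 0, n_per_grade: int = 60, dict_size: int = 64
) -> PipelineConfig:
    """The package's reference experiment: 60 synthetic images per grade,
    64 visual words per modality, all four single-modality baselines."""
    return PipelineConfig(
        synth=SynthConfig(counts=(n_per_grade,) * 3, seed=seed),
        dict_size_color=dict_size,
        dict_size_surf=dict_size,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full experiment described by ``config``.

    Returns per-model evaluation reports (key ``"jmbof"`` plus one per
    configured baseline), the fitted JMBoF model, and the run manifest.
    """
    cfg = config
    log: dict = {"seed": cfg.seed, "stages": []}
    t_start = time.perf_counter()

    # --- stage: dataset -------------------------------------------------
    if cfg.data_dir is not None:
        images = load_dataset_dir(cfg.data_dir)
    elif cfg.synth is not None:
        images, _ = generate_dataset(cfg.synth)
    else:
        raise ValueError("stage dataset: need data_dir or a synth config")
    labels = np.array([im.label for im in images])
    if any(l is None for l in labels):
        raise ValueError("stage dataset: all images must carry a grade label")
    log["n_images"] = len(images)
    log["stages"].append("dataset")

    # --- stage: split ---------------------------------------------------
    index_set = classify.LabeledFeatureSet(
        np.arange(len(images), dtype=float)[:, None],
        labels,
        np.array([im.id for im in images]),
    )
    tr_set, te_set = classify.stratified_split(
        index_set, train_fraction=cfg.train_fraction, seed=cfg.seed
    )
    tr_idx = tr_set.features[:, 0].astype(int)
    te_idx = te_set.features[:, 0].astype(int)
    y_train, y_test = labels[tr_idx], labels[te_idx]
    log["split_counts"] = {"train": len(tr_idx), "test": len(te_idx)}
    log["stages"].append("split")

    # --- stage: features ------------------------------------------------
    need = {"lab", "surf"} | set(cfg.baselines)
    feats = _extract_all(images, cfg, need, log)
    log["stages"].append("features")

    # --- stage: dictionaries (training images only) ----------------------
    t0 = time.perf_counter()
    dicts = {}
    sizes = {
        "lab": cfg.dict_size_color,
        "rgb": cfg.dict_size_color,
        "hsi": cfg.dict_size_color,
        "surf": cfg.dict_size_surf,
    }
    for m in sorted(need):
        train_feats = np.vstack([feats[m][i] for i in tr_idx])
        k = min(sizes[m], train_feats.shape[0])
        dicts[m] = bof.build_dictionary(
            train_feats,
            k=k,
            seed=cfg.seed + 1,
            modality="surf" if m == "surf" else "color",
        )
    log["dictionary_sizes"] = {m: dicts[m].k for m in dicts}
    log["dict_seconds"] = round(time.perf_counter() - t0, 3)
    log["stages"].append("dictionaries")

    # --- stage: encoding -------------------------------------------------
    hists = {m: _encode_all(feats[m], dicts[m]) for m in sorted(need)}
    joint = np.hstack([hists["lab"], hists["surf"]])  # (n, k_c + k_s)
    log["stages"].append("encoding")

    # --- stage: low-rank fusion ------------------------------------------
    t0 = time.perf_counter()
    if cfg.transductive:
        # decompose the complete descriptor matrix jointly and classify
        # the denoised low-rank coordinates (the printed method read
        # literally: Eq. 4 is applied to the whole descriptor set)
        Y = joint.T  # (d, n): columns are samples
        lam = cfg.lam or cfg.lam_scale / np.sqrt(max(Y.shape))
        dec = lowrank.rpca_decompose(Y, lam=lam)
        basis = lowrank.fit_lowrank_basis(dec.X, energy=cfg.energy)
        reduced = lowrank.project_descriptors(basis, dec.X).T
        Z_train, Z_test = reduced[tr_idx], reduced[te_idx]
    else:
        Y = joint[tr_idx].T
        lam = cfg.lam or cfg.lam_scale / np.sqrt(max(Y.shape))
        dec = lowrank.rpca_decompose(Y, lam=lam)
        basis = lowrank.fit_lowrank_basis(dec.X, energy=cfg.energy)
        Z_train = lowrank.project_descriptors(basis, joint[tr_idx].T).T
        Z_test = lowrank.project_descriptors(basis, joint[te_idx].T).T
    log["lowrank"] = {
        "rank": basis.rank,
        "lambda": dec.lam,
        "residual": dec.residual,
        "iterations": dec.iterations,
        "converged": dec.converged,
    }
    log["lowrank_seconds"] = round(time.perf_counter() - t0, 3)
    log["stages"].append("lowrank")

    # --- stage: classifiers ----------------------------------------------
    t0 = time.perf_counter()
    svm_cfg = cfg.svm or classify.SvmConfig(seed=cfg.seed + 2)
    reports: dict[str, ModelReport] = {}
    jm_model = classify.train_classifier(
        classify.LabeledFeatureSet(Z_train, y_train, tr_set.ids), svm_cfg
    )
    reports["jmbof"] = _evaluate_model(
        "jmbof", jm_model, Z_train, y_train, Z_test, y_test
    )
    for m in cfg.baselines:
        Xb_tr, Xb_te = hists[m][tr_idx], hists[m][te_idx]
        bmodel = classify.train_classifier(
            classify.LabeledFeatureSet(Xb_tr, y_train, tr_set.ids), svm_cfg
        )
        reports[m] = _evaluate_model(
            m, bmodel, Xb_tr, y_train, Xb_te, y_test
        )
    log["svm_seconds"] = round(time.perf_counter() - t0, 3)
    log["stages"].append("classify")
    log["stages"].append("evaluate")

    log["metrics"] = [reports[name].summary() for name in reports]
    log["total_seconds"] = round(time.perf_counter() - t_start, 3)

    model = PipelineModel(
        color_dict=dicts["lab"],
        surf_dict=dicts["surf"],
        lowrank_model=basis,
        classifier=jm_model,
        config=cfg,
    )
    return PipelineResult(reports=reports, model=model, manifest=log)


def save_model(model: PipelineModel, path) -> str:
    """Persist a fitted pipeline model; returns the file's SHA-256 hash."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "color_dict": model.color_dict,
        "surf_dict": model.surf_dict,
        "lowrank_model": model.lowrank_model,
        "classifier": model.classifier,
        "config": model.config,
    }
    joblib.dump(payload, path)
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def load_model(path) -> PipelineModel:
    """Load a persisted model; a truncated or alien file raises cleanly."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib/pickle raise a zoo of error types
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if (
        not isinstance(payload, dict)
        or payload.get("format_version") != MODEL_FORMAT_VERSION
    ):
        raise ModelIOError(
            f"{path} is not a model file of format version "
            f"{MODEL_FORMAT_VERSION}"
        )
    return PipelineModel(
        color_dict=payload["color_dict"],
        surf_dict=payload["surf_dict"],
        lowrank_model=payload["lowrank_model"],
        classifier=payload["classifier"],
        config=payload["config"],
    )
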