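"""End-to-end orchestration: screen -> fit MLR/ANN/SVR -> predict the
sunscreen queries -> aggregate means -> applicability domain -> atomic
contributions, with deterministic per-stage seeds and CSV/markdown reports.

The flagship output mirrors the package's prediction table layout: one row
per query compound with its six descriptors, per-model pIC50 predictions
(MLR, ANN1, SVR, and ANN2..ANN5 when five networks are retained), the
arithmetic mean columns Mean(1) = mean(MLR, ANN1, SVR) and Mean(2) (all
retained ANNs included), and a qualitative inhibition-strength label.
"""

from __future__ import annotations

import importlib.resources
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ann as ann_mod
from . import applicability as ad_mod
from . import atom_contrib as atom_mod
from . import mlr as mlr_mod
from . import screening as screening_mod
from . import svr as svr_mod
from . import synthetic as synth_mod
from .data import Dataset, MODELING_DESCRIPTORS, random_split, read_compound_table

STAGES = ("screen", "mlr", "ann", "svr", "predict", "ad", "atoms")


class PipelineError(RuntimeError):
    pass


def packaged_fixture(name: str = "sunscreens_table2.csv"):
    """Path to a packaged dataset (the 16-sunscreen query table by default)."""
    return importlib.resources.files("sunqsar.datasets") / name


def load_sunscreens() -> Dataset:
    return read_compound_table(packaged_fixture())


def load_toy_smiles() -> pd.DataFrame:
    return pd.read_csv(packaged_fixture("toy_smiles_synthetic.csv"))


def classify_inhibition_strength(pic50: float) -> str:
    """Qualitative potency band for a predicted pIC50.

    Bands are closed on the left, open on the right, except [5, 6] which is
    closed on both sides ("between 5 and 6" inclusive); values above 6 are
    flagged for an applicability-domain check.
    """
    if not np.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    if pic50 < 2:
        return "weak"
    if pic50 < 4:
        return "moderate"
    if pic50 < 5:
        return "comparable-to-reference-drugs"
    if pic50 <= 6:
        return "strong"
    return "very-high (check AD)"


@dataclass
class PipelineConfig:
    """Flat configuration; loadable from a YAML key/value document."""

    seed: int = 0
    outdir: str | None = None
    reference_path: str | None = None   # None -> synthetic reference
    query_path: str | None = None       # None -> packaged sunscreen fixture
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    n_reference: int = 121
    sigma: float = 0.59
    train_fraction: float = 100 / 121
    ann_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    ann_n_train: int = 40
    ann_n_retain: int = 5
    svr_kernel: str = "linear"
    ad_coverage: float = 0.99
    use_toy_smiles: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s) {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if abs(sum(self.ann_fractions) - 1.0) > 1e-9:
            raise PipelineError("ann_fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise PipelineError("config must be a mapping")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(doc) - allowed
        if unknown:
            raise PipelineError(f"unknown config key(s) {sorted(unknown)}")
        if "ann_fractions" in doc:
            doc["ann_fractions"] = tuple(doc["ann_fractions"])
        return cls(**doc)

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(STAGES) + 1)
        seeds = {s: int(c.generate_state(1)[0] % (2 ** 31))
                 for s, c in zip(STAGES, children)}
        seeds["reference"] = int(children[-1].generate_state(1)[0] % (2 ** 31))
        return seeds


@dataclass
class ReportBundle:
    predictions: pd.DataFrame | None = None
    correlation: pd.DataFrame | None = None
    tolerance: pd.DataFrame | None = None
    fit_stats: pd.DataFrame | None = None
    ad_verdicts: pd.DataFrame | None = None
    gsa: pd.DataFrame | None = None
    svr_metrics: pd.DataFrame | None = None
    atom_contributions: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name in ("predictions", "correlation", "tolerance", "fit_stats",
                     "ad_verdicts", "gsa", "svr_metrics", "atom_contributions"):
            tbl = getattr(self, name)
            if tbl is not None:
                out[name] = tbl
        return out

    def is_empty(self) -> bool:
        return not self.tables()


def run(config: PipelineConfig, raise_on_failure: bool = True) -> ReportBundle:
    """Execute the enabled stages in dependency order.

    A failing stage aborts its downstream dependents but independent stages
    still run; failures are collected on the bundle and raised at the end
    (unless ``raise_on_failure=False``).
    """
    bundle = ReportBundle()
    seeds = config.stage_seeds()
    enabled = {s for s in STAGES if config.stages.get(s, True)}
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds,
                      "stages": sorted(enabled), "timings": {}}
    bundle.manifest = manifest

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            bundle.failures[stage] = f"{type(exc).__name__}: {exc}"
        manifest["timings"][stage] = round(time.perf_counter() - t0, 3)

    needs_reference = enabled & {"screen", "mlr", "ann", "svr", "ad", "atoms"}
    reference = None
    if needs_reference:
        if config.reference_path:
            reference = read_compound_table(config.reference_path)
        else:
            toy = load_toy_smiles() if config.use_toy_smiles else None
            reference = synth_mod.generate(
                synth_mod.SyntheticConfig(n=config.n_reference,
                                          sigma=config.sigma,
                                          seed=seeds["reference"]),
                smiles_library=toy)
        reference = random_split(
            reference,
            {"train": config.train_fraction, "test": 1 - config.train_fraction},
            seed=seeds["reference"])
        manifest["n_reference"] = len(reference)

    query = (read_compound_table(config.query_path) if config.query_path
             else load_sunscreens())
    manifest["n_query"] = len(query)

    models: dict[str, object] = {}

    if "screen" in enabled:
        def _screen():
            cm = screening_mod.correlation_matrix(
                reference, names=tuple(MODELING_DESCRIPTORS) + ("pIC50",))
            bundle.correlation = cm.to_frame()
            rep = screening_mod.screen_subset(reference, MODELING_DESCRIPTORS)
            bundle.tolerance = rep.to_frame()
        timed("screen", _screen)

    if "mlr" in enabled:
        def _mlr():
            model = mlr_mod.fit_ols(reference, split="train")
            model.stats.q2_loo = mlr_mod.q2_loo(reference, split="train")
            mlr_mod.evaluate_test(model, reference, split="test")
            models["mlr"] = model
            s = model.stats
            bundle.fit_stats = pd.DataFrame([{
                "model": "MLR(refit)", "n": s.n, "k": s.k, "R2": s.r2,
                "R2_adj": s.r2_adj, "Q2_LOO": s.q2_loo, "F": s.f_stat,
                "p": s.p_value, "RMSE_pred": s.rmse_pred,
            }])
        timed("mlr", _mlr)

    if "ann" in enabled:
        def _ann():
            tr, te, va = config.ann_fractions
            ann_ds = random_split(reference,
                                  {"train": tr, "test": te, "validation": va},
                                  seed=seeds["ann"])
            retained = ann_mod.automated_search(
                ann_ds, n_train_networks=config.ann_n_train,
                n_retain=config.ann_n_retain, seed=seeds["ann"])
            models["ann"] = retained
            report = ann_mod.gsa(retained[0], ann_ds, split="train")
            bundle.gsa = report.to_frame()
        timed("ann", _ann)

    if "svr" in enabled:
        def _svr():
            model = svr_mod.fit_svr(reference, kernel=config.svr_kernel,
                                    split="train")
            models["svr"] = model
            bundle.svr_metrics = svr_mod.metrics_table(
                model,
                (reference.subset("train").descriptor_matrix(),
                 reference.subset("train").response()),
                (reference.subset("test").descriptor_matrix(),
                 reference.subset("test").response()))
        timed("svr", _svr)

    if "predict" in enabled:
        def _predict():
            rows = []
            for rec in query.records:
                row = {"id": rec.id}
                row.update({n: rec.descriptors.get(n, np.nan)
                            for n in MODELING_DESCRIPTORS})
                preds = {"MLR": mlr_mod.predict_published(rec)}
                if "mlr" in models:
                    row["MLR_refit"] = models["mlr"].predict_one(rec)
                if "ann" in models:
                    x = np.array([[rec.descriptors[n]
                                   for n in MODELING_DESCRIPTORS]])
                    for i, net in enumerate(models["ann"], start=1):
                        preds[f"ANN{i}"] = float(net.predict(x)[0])
                if "svr" in models:
                    x = np.array([[rec.descriptors[n]
                                   for n in MODELING_DESCRIPTORS]])
                    preds["SVR"] = float(models["svr"].predict(x)[0])
                row.update(preds)
                if {"MLR", "ANN1", "SVR"} <= set(preds):
                    sets = {"Mean(1)": ("MLR", "ANN1", "SVR")}
                    ann_names = sorted(
                        (p for p in preds if p.startswith("ANN")),
                        key=lambda s: int(s[3:]))
                    if len(ann_names) >= 5:
                        sets["Mean(2)"] = ("MLR", *ann_names[:5], "SVR")
                    row.update(mlr_mod.aggregate_means(preds, sets))
                    row["strength"] = classify_inhibition_strength(row["Mean(1)"])
                else:
                    row["strength"] = classify_inhibition_strength(preds["MLR"])
                rows.append(row)
            bundle.predictions = pd.DataFrame(rows)
        timed("predict", _predict)

    if "ad" in enabled:
        def _ad():
            model = ad_mod.fit_ad(reference, coverage=config.ad_coverage)
            verdicts = ad_mod.classify(model, query)
            bundle.ad_verdicts = ad_mod.verdicts_frame(verdicts)
        timed("ad", _ad)

    if "atoms" in enabled:
        def _atoms():
            with_smiles = [r for r in reference.records if r.smiles]
            if len(with_smiles) < 10:
                raise PipelineError("atoms stage needs SMILES on the reference set")
            pls = atom_mod.train_pls(reference, seed=seeds["atoms"])
            mols = {(r.id, r.smiles) for r in reference.records if r.smiles}
            # one map per distinct structure keeps the table small
            seen, pairs = set(), []
            for cid, smi in sorted(mols):
                if smi not in seen:
                    seen.add(smi)
                    pairs.append((cid, smi))
            bundle.atom_contributions = atom_mod.contributions_table(pls, pairs)
            manifest["pls_q2_cv"] = pls.q2_cv
            manifest["pls_r2_test"] = pls.r2_test
        timed("atoms", _atoms)

    if config.outdir:
        write_outputs(bundle, config.outdir)
    if bundle.failures and raise_on_failure:
        raise PipelineError(f"stage failures: {bundle.failures}")
    return bundle


def write_outputs(bundle: ReportBundle, outdir) -> None:
    """Write every produced table as CSV plus a manifest and summary report.

    Output is deterministic for a fixed config/seed apart from the
    ``timings`` block of the manifest.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tbl in bundle.tables().items():
        tbl.to_csv(out / f"{name}.csv",
                   index=name in ("correlation", "svr_metrics"))
    with open(out / "manifest.json", "w") as fh:
        json.dump({**bundle.manifest, "failures": bundle.failures},
                  fh, indent=2, default=str)
    lines = ["# Run report", ""]
    if bundle.predictions is not None:
        disp = bundle.predictions.copy()
        for c in disp.columns:
            if disp[c].dtype.kind == "f":
                disp[c] = disp[c].map(lambda v: f"{v:.2f}")
        lines += ["## Predicted pIC50 (2-decimal display)", "",
                  disp.to_string(index=False), ""]
    if bundle.ad_verdicts is not None:
        outside = bundle.ad_verdicts.query("~inside")["id"].tolist()
        lines += ["## Applicability domain", "",
                  f"Outside the reference chemical space: {outside or 'none'}",
                  ""]
    if bundle.failures:
        lines += ["## Stage failures", ""] + [
            f"- {k}: {v}" for k, v in bundle.failures.items()]
    (out / "report.md").write_text("\n".join(lines))
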