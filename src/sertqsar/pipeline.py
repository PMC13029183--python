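"""Full study replica: data -> splits -> MC QSAR -> GA-MLR -> validation ->
applicability domain -> candidate design -> structure-score analytics.

``run_study`` orchestrates every stage over synthetic (default) or loaded
inputs and returns one consolidated, JSON-serializable report with
per-split, per-run metric tables plus averaged rows, AD summaries, ranked
candidates, and docking-score correlations.  Re-running with the same
config reproduces the report (all randomness flows from the config seeds).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import ad as ad_mod
from . import design as design_mod
from .attributes import extract_inventory
from .dataset import CompoundRecord, SplitSpec, make_split, read_dataset
from .gamlr import GAConfig, ga_select, preprocess
from .mc import select_hyperparams
from .metrics import basic_stats, leverage_ad, mae_classify, q2_loo, y_randomization
from .scores import comp_score, correlate_scores, load_score_table, pers_score, pose_score
from .simulate import (
    ScaffoldSpec,
    gen_descriptor_matrix,
    gen_pose_trajectories,
    gen_scaffold_dataset,
)

__all__ = ["PipelineConfig", "run_study", "save_report", "packaged_table"]


@dataclass
class PipelineConfig:
    seed: int = 0
    dataset_path: str | None = None  # None -> synthetic scaffold series
    n_compounds: int = 50
    noise_sd: float = 0.1
    n_splits: int = 3
    train_fraction: float = 0.75
    # Monte Carlo branch
    t_values: tuple = (1, 2, 3)
    epoch_max: int = 50
    n_runs: int = 3
    # GA-MLR branch (descriptor matrix is synthetic unless a path is given)
    descriptor_path: str | None = None
    ga: GAConfig = field(default_factory=lambda: GAConfig(generations=100))
    # Y-randomization (scaled down from the 1000x10 battery for routine runs)
    yrand_permutations: int = 100
    yrand_runs: int = 3
    # candidate design
    design_substituents: tuple = ("F", "CC(C)", "N#C")


def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables (TSV).

    Full-line '#' comments are stripped; '#' elsewhere is data (nitrile
    SMILES), so pandas' comment handling must not see it.
    """
    import io

    text = resources.files("sertqsar.data").joinpath(name).read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return pd.read_csv(io.StringIO(body), sep="\t")


def _linear_fitter(X, y):
    X = np.asarray(X, dtype=float).reshape(len(y), -1)
    coef = np.polyfit(X[:, 0], y, 1)
    return lambda Xn: np.polyval(coef, np.asarray(Xn, dtype=float).reshape(-1))


def _mc_branch(records, inventories, cfg: PipelineConfig) -> dict:
    out: dict = {"splits": {}}
    for s in range(1, cfg.n_splits + 1):
        split = make_split(records, SplitSpec(split_index=s, seed=cfg.seed))
        tr = [r for r in split if r.subset == "train"]
        te = [r for r in split if r.subset == "test"]
        it = [inventories[r.id] for r in tr]
        ie = [inventories[r.id] for r in te]
        yt = np.array([r.pic50 for r in tr])
        ye = np.array([r.pic50 for r in te])
        runs = []
        best = None
        for run in range(cfg.n_runs):
            T, ne, model, _ = select_hyperparams(
                it, yt, ie, ye,
                t_values=cfg.t_values,
                epoch_max=cfg.epoch_max,
                seed=cfg.seed * 1000 + s * 10 + run,
            )
            pt = np.array([model.predict(i) for i in it])
            pe = np.array([model.predict(i) for i in ie])
            dcw_t = (pt - model.c0) / model.c1
            row = {
                "run": run + 1,
                "T": T,
                "n_epoch": ne,
                "c0": model.c0,
                "c1": model.c1,
                "train": basic_stats(yt, pt),
                "test": basic_stats(ye, pe),
            }
            row["train"]["q2"] = q2_loo(_linear_fitter, dcw_t.reshape(-1, 1), yt)
            runs.append(row)
            if best is None or row["test"]["r2"] > best[0]:
                best = (row["test"]["r2"], model, tr, te, it, ie, yt, ye)
        av = {
            part: {
                k: float(np.mean([r[part][k] for r in runs]))
                for k in runs[0][part]
                if k != "n"
            }
            for part in ("train", "test")
        }
        _, model, tr, te, it, ie, yt, ye = best
        # applicability domain on the best run's split
        rep = ad_mod.defect_report(it, ie)
        mae_cls = mae_classify(
            ye, np.array([model.predict(i) for i in ie]), float(yt.max() - yt.min())
        )
        out["splits"][s] = {
            "runs": runs,
            "average": av,
            "n_train": len(tr),
            "n_test": len(te),
            "mae_class_test": mae_cls,
            "ad": {
                "dav_train": rep.dav_train,
                "dav_test": rep.dav_test,
                "n_outliers": int(sum(rep.outlier.values())),
            },
            "_model": model,
            "_train": (tr, it, yt),
        }
    return out


def _gamlr_branch(cfg: PipelineConfig, rng) -> dict:
    if cfg.descriptor_path:
        df = pd.read_csv(cfg.descriptor_path)
        from .gamlr import DescriptorMatrix

        matrix = DescriptorMatrix.from_frame(df)
        raise NotImplementedError(
            "external descriptor matrices need joined activities; use the API"
        )
    matrix, y, truth = gen_descriptor_matrix(
        n=60, p=50, k_signal=cfg.ga.k, noise_sd=0.1,
        seed=cfg.seed + 77, n_collinear=3, n_constant=2,
    )
    pre = preprocess(matrix, activities=y)
    model = ga_select(pre, y, cfg.ga)
    pred = model.predict(pre.X[:, [pre.names.index(n) for n in model.names]])
    resid = y - pred
    lev = leverage_ad(pre.X[:, [pre.names.index(n) for n in model.names]], resid)
    recovered = sorted(n.split("_")[0] for n in model.names)
    return {
        "selected": model.names,
        "planted": truth["signal"],
        "recovered_all": set(recovered) == set(truth["signal"]),
        "fitness_q2loo": model.fitness,
        "train": basic_stats(y, pred),
        "leverage": {
            "h_star": lev.h_star,
            "sum_h": float(lev.h.sum()),
            "n_leverage_out": int(lev.leverage_out.sum()),
            "n_response_out": int(lev.response_out.sum()),
        },
    }


def _design_branch(mc_out: dict, cfg: PipelineConfig) -> dict:
    # use the best split's best model to rank candidates on the packaged parent
    best_s = max(
        mc_out["splits"], key=lambda s: mc_out["splits"][s]["average"]["test"]["r2"]
    )
    model = mc_out["splits"][best_s]["_model"]
    tail = "c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F"
    sites = [
        design_mod.SubstitutionSite("ortho", "{}c1ccccc1" + tail),
        design_mod.SubstitutionSite("meta", "{}c1cccc(c1)" + tail),
        design_mod.SubstitutionSite("para", "{}c1ccc(cc1)" + tail),
    ]
    cands = design_mod.enumerate_candidates(
        sites, list(cfg.design_substituents), parent="A"
    )
    ranked = design_mod.score_candidates(cands, model)
    return {
        "split_used": best_s,
        "n_candidates": len(ranked),
        "candidates": [
            {
                "smiles": c.smiles,
                "edit": c.edit,
                "pic50_pred": c.pic50_pred,
                "ic50_nM": c.ic50_nm,
                "novel_attributes": c.novel_attributes,
            }
            for c in ranked
        ],
    }


def _scores_branch(cfg: PipelineConfig) -> dict:
    table = packaged_table("docking_scores.tsv")
    corr = {}
    for col in ("MolDock", "Rerank"):
        for method in ("pearson", "spearman"):
            r, p = correlate_scores(table, col, "pIC50", method)
            corr[f"{col}_{method}"] = {"coefficient": r, "p": p}
    bpmd = {}
    for label, stable in (("stable", True), ("unstable", False)):
        traj = gen_pose_trajectories(stable=stable, seed=cfg.seed + 5)
        ps, prs = pose_score(traj), pers_score(traj)
        bpmd[label] = {
            "pose_score": ps,
            "pers_score": prs,
            "comp_score": comp_score(ps, prs),
        }
    return {"docking_correlations": corr, "bpmd": bpmd}


def run_study(config: PipelineConfig | None = None) -> dict:
    """Run every pipeline stage; returns the consolidated report."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    if cfg.dataset_path:
        records = read_dataset(cfg.dataset_path)
        truth = None
    else:
        records, truth = gen_scaffold_dataset(
            ScaffoldSpec(n=cfg.n_compounds, noise_sd=cfg.noise_sd, seed=cfg.seed)
        )
    inventories = {r.id: extract_inventory(r.smiles, r.id) for r in records}

    stage_errors: dict[str, str] = {}
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()}}
    try:
        mc_out = _mc_branch(records, inventories, cfg)
        report["mc_qsar"] = {
            "splits": {
                s: {k: v for k, v in d.items() if not k.startswith("_")}
                for s, d in mc_out["splits"].items()
            }
        }
    except Exception as exc:  # noqa: BLE001
        stage_errors["mc_qsar"] = str(exc)
        mc_out = None
    try:
        report["ga_mlr"] = _gamlr_branch(cfg, rng)
    except Exception as exc:  # noqa: BLE001
        stage_errors["ga_mlr"] = str(exc)
    if mc_out is not None:
        try:
            report["design"] = _design_branch(mc_out, cfg)
        except Exception as exc:  # noqa: BLE001
            stage_errors["design"] = str(exc)
        try:
            s = 1
            model = mc_out["splits"][s]["_model"]
            tr, it, yt = mc_out["splits"][s]["_train"]
            dcw = np.array(
                [(model.predict(i) - model.c0) / model.c1 for i in it]
            ).reshape(-1, 1)
            yr = y_randomization(
                _linear_fitter, dcw, yt,
                n_permutations=cfg.yrand_permutations,
                n_runs=cfg.yrand_runs,
                seed=cfg.seed + 13,
            )
            report["y_randomization"] = asdict(yr)
        except Exception as exc:  # noqa: BLE001
            stage_errors["y_randomization"] = str(exc)
    try:
        report["structure_scores"] = _scores_branch(cfg)
    except Exception as exc:  # noqa: BLE001
        stage_errors["structure_scores"] = str(exc)
    report["stage_errors"] = stage_errors
    report["ok"] = not stage_errors
    return report


def save_report(report: dict, out_dir) -> Path:
    """Write the JSON master report plus flat TSV metric tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    if "mc_qsar" in report:
        rows = []
        for s, d in report["mc_qsar"]["splits"].items():
            for r in d["runs"]:
                rows.append(
                    {"split": s, "run": r["run"], "T": r["T"], "n_epoch": r["n_epoch"],
                     **{f"train_{k}": v for k, v in r["train"].items()},
                     **{f"test_{k}": v for k, v in r["test"].items()}}
                )
            rows.append(
                {"split": s, "run": "Av",
                 **{f"train_{k}": v for k, v in d["average"]["train"].items()},
                 **{f"test_{k}": v for k, v in d["average"]["test"].items()}}
            )
        pd.DataFrame(rows).to_csv(out / "mc_metrics.tsv", sep="\t", index=False)
    if "design" in report:
        pd.DataFrame(report["design"]["candidates"]).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
    return out / "report.json"
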