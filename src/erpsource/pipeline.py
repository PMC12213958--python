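"""Desk-scale study orchestration: simulate -> preprocess -> ERP ->
forward -> inverse -> group stats -> report, with deterministic seeding,
a JSON run manifest (parameters, input/output hashes, wall times,
warnings) and bit-exact artifact caching."""

from __future__ import annotations

import dataclasses
import json
import os
import shutil
import time
import warnings as _warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as erp_mod
from .config import PipelineConfig, build_geometry
from .containers import (
    load_epochs,
    load_leadfield,
    save_epochs,
    save_leadfield,
    save_masks,
    sha256_of,
    write_montage_sfp,
)
from .forward import compute_leadfield
from .inverse import (
    apply_inverse_window,
    cdr_scores,
    make_inverse_operator,
    roi_aggregate,
)
from .preprocess import preprocess
from .simulate import CONDITIONS, simulate_study
from .stats import build_stat_report

__all__ = ["Pipeline", "STAGES"]

STAGES = ("forward", "simulate", "preprocess", "erp", "inverse", "stats", "report")
_DEPS = {
    "forward": (),
    "simulate": ("forward",),
    "preprocess": ("simulate",),
    "erp": ("preprocess",),
    "inverse": ("forward", "preprocess", "erp"),
    "stats": ("inverse",),
    "report": ("stats",),
}


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


class Pipeline:
    """Stage runner over one output directory, driven by a single config."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.out / "manifest.json"

    # -- geometry is cheap and fully determined by the config ------------
    def geometry(self):
        return build_geometry(self.config)

    # -- manifest / caching ---------------------------------------------
    def _manifest(self) -> dict:
        if self._manifest_path.exists():
            return json.loads(self._manifest_path.read_text())
        return {"config": self.config.to_dict(), "stages": {}}

    def _save_manifest(self, manifest: dict) -> None:
        _atomic_write_text(self._manifest_path, json.dumps(manifest, indent=1))

    def _stage_params(self, stage: str) -> dict:
        cfg = self.config.to_dict()
        cfg["out_dir"] = "."  # location must not invalidate the cache
        return cfg

    def _is_cached(self, stage: str, manifest: dict) -> bool:
        entry = manifest["stages"].get(stage)
        if not entry:
            return False
        if entry["params"] != _jsonround(self._stage_params(stage)):
            return False
        for rel, digest in entry["outputs"].items():
            p = self.out / rel
            if not p.exists() or sha256_of(p) != digest:
                return False
        return True

    # -- public API ------------------------------------------------------
    def run_stage(self, stage: str, force: bool = False) -> dict:
        """Run one stage (dependencies must already have run; ``simulate``
        bootstraps ``forward`` itself).  Returns the manifest entry."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
        manifest = self._manifest()
        if not force and self._is_cached(stage, manifest):
            entry = dict(manifest["stages"][stage])
            entry["skipped"] = True
            return entry
        for dep in _DEPS[stage]:
            if not self._is_cached(dep, manifest):
                if stage == "simulate":
                    self.run_stage(dep, force=force)
                    manifest = self._manifest()
                else:
                    raise RuntimeError(
                        f"missing inputs for stage {stage!r}: run {dep!r} first"
                    )
        t0 = time.perf_counter()
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            outputs = getattr(self, f"_stage_{stage}")()
        entry = {
            "params": _jsonround(self._stage_params(stage)),
            "outputs": {rel: sha256_of(self.out / rel) for rel in outputs},
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "warnings": [str(w.message) for w in caught],
            "skipped": False,
        }
        manifest = self._manifest()
        manifest["stages"][stage] = entry
        self._save_manifest(manifest)
        return entry

    def run_all(self, force: bool = False) -> dict:
        for stage in STAGES:
            self.run_stage(stage, force=force)
        return self._manifest()

    # -- stages ----------------------------------------------------------
    def _stage_forward(self) -> list[str]:
        head, montage, src, masks = self.geometry()
        lf = compute_leadfield(head, src, montage, self.config.inverse.truncation_L)
        fdir = self.out / "forward"
        fdir.mkdir(exist_ok=True)
        write_montage_sfp(montage, fdir / "montage.sfp", fiducials=head.fiducials)
        save_masks(masks, fdir / "masks.json")
        save_leadfield(lf, fdir / "leadfield")
        np.save(fdir / "source_positions.npy", src.positions)
        return [
            "forward/montage.sfp",
            "forward/masks.json",
            "forward/leadfield.npy",
            "forward/leadfield.json",
            "forward/source_positions.npy",
        ]

    def _stage_simulate(self) -> list[str]:
        head, montage, src, masks = self.geometry()
        lf = load_leadfield(self.out / "forward" / "leadfield")
        truth = self.config.truth.resolve(masks)
        study_dir = self.out / "study"
        if study_dir.exists():
            shutil.rmtree(study_dir)
        simulate_study(
            self.config.design, head, montage, src, masks, truth, lf, study_dir
        )
        outputs = ["study/manifest.json", "study/truth.json", "study/masks.json",
                   "study/montage.sfp"]
        for i in range(self.config.design.n_subjects):
            outputs += [f"study/S{i:02d}/epochs.npy", f"study/S{i:02d}/epochs.json"]
        return outputs

    def _stage_preprocess(self) -> list[str]:
        _, montage, _, _ = self.geometry()
        pdir = self.out / "preprocessed"
        pdir.mkdir(exist_ok=True)
        reports = []
        outputs = []
        for i in range(self.config.design.n_subjects):
            sid = f"S{i:02d}"
            epochs = load_epochs(self.out / "study" / sid / "epochs")
            clean, report = preprocess(epochs, self.config.preproc, montage)
            if not report.excluded:
                save_epochs(clean, pdir / sid / "epochs")
                outputs += [f"preprocessed/{sid}/epochs.npy",
                            f"preprocessed/{sid}/epochs.json"]
            reports.append(report.to_dict())
        _atomic_write_text(pdir / "exclusions.json", json.dumps(reports, indent=1))
        outputs.append("preprocessed/exclusions.json")
        return outputs

    def _included_subjects(self) -> list[str]:
        reports = json.loads(
            (self.out / "preprocessed" / "exclusions.json").read_text()
        )
        return [r["subject_id"] for r in reports if not r["excluded"]]

    def _stage_erp(self) -> list[str]:
        _, montage, _, _ = self.geometry()
        edir = self.out / "erp"
        edir.mkdir(exist_ok=True)
        subjects = self._included_subjects()
        if not subjects:
            raise RuntimeError("no included subjects after preprocessing")
        all_epochs = {
            sid: load_epochs(self.out / "preprocessed" / sid / "epochs")
            for sid in subjects
        }
        _, p2_range, lsw_range = erp_mod.collapsed_localizer(
            list(all_epochs.values()), montage
        )
        wcfg = self.config.windows
        windows = {}
        for sid, ep in all_epochs.items():
            p2 = erp_mod.locate_p2_window(ep, montage, wcfg.p2_search_ms,
                                          wcfg.p2_window_ms)
            lsw = erp_mod.locate_lsw_window(
                wcfg.lsw_window_ms, self.config.design.epoch_ms
            )
            windows[sid] = {"P2": dataclasses.asdict(p2), "LSW": dataclasses.asdict(lsw)}
        _atomic_write_text(
            edir / "windows.json",
            json.dumps({"localizer_p2_range_ms": list(p2_range),
                        "localizer_lsw_range_ms": list(lsw_range),
                        "subjects": windows}, indent=1),
        )
        outputs = ["erp/windows.json"]
        for comp in ("P2", "LSW"):
            frames = []
            for sid, ep in all_epochs.items():
                w = erp_mod.ComponentWindow(**windows[sid][comp])
                reb = erp_mod.rebaseline(ep, w)
                cm = erp_mod.cluster_means(reb, w, montage)
                cm.insert(0, "subject", sid)
                frames.append(cm)
            amps = pd.concat(frames, ignore_index=True)
            amps.to_csv(edir / f"cluster_amplitudes_{comp}.tsv", sep="\t", index=False)
            anova = erp_mod.rm_anova_2x3x3(amps)
            anova.effects.to_csv(edir / f"anova_{comp}.tsv", sep="\t")
            post = erp_mod.emm_tukey_posthoc(amps, anova, by="cell")
            post.to_csv(edir / f"posthoc_{comp}.tsv", sep="\t", index=False)
            outputs += [
                f"erp/cluster_amplitudes_{comp}.tsv",
                f"erp/anova_{comp}.tsv",
                f"erp/posthoc_{comp}.tsv",
            ]
        return outputs

    def _stage_inverse(self) -> list[str]:
        _, montage, src, masks = self.geometry()
        lf = load_leadfield(self.out / "forward" / "leadfield")
        icfg = self.config.inverse
        op = make_inverse_operator(
            lf, alpha=icfg.alpha, tol=icfg.tol, max_iter=icfg.max_iter
        )
        idir = self.out / "inverse"
        idir.mkdir(exist_ok=True)
        np.save(idir / "operator.npy", op.operator)
        _atomic_write_text(
            idir / "operator.json",
            json.dumps({"alpha": op.alpha, "n_iter": op.n_iter,
                        "converged": op.converged,
                        "shape": list(op.operator.shape)}, indent=1),
        )
        windows = json.loads((self.out / "erp" / "windows.json").read_text())
        mask_meta = {m.name: m for m in masks}
        rows = []
        for sid in self._included_subjects():
            ep = load_epochs(self.out / "preprocessed" / sid / "epochs")
            for comp in ("P2", "LSW"):
                w = erp_mod.ComponentWindow(**windows["subjects"][sid][comp])
                reb = erp_mod.rebaseline(ep, w)
                for cond in CONDITIONS:
                    mom = apply_inverse_window(op, reb, w, cond)
                    cdr = cdr_scores(mom)
                    for roi, val in roi_aggregate(cdr, masks).items():
                        m = mask_meta[roi]
                        rows.append(
                            {
                                "subject": sid,
                                "component": comp,
                                "roi": roi,
                                "family": m.family,
                                "hemisphere": m.hemisphere,
                                "condition": cond,
                                "cdr": val,
                                "n_grid": int(m.indices.size),
                            }
                        )
        pd.DataFrame(rows).to_csv(idir / "roi_cdr.tsv", sep="\t", index=False)
        return ["inverse/operator.npy", "inverse/operator.json", "inverse/roi_cdr.tsv"]

    def _stage_stats(self) -> list[str]:
        _, _, _, masks = self.geometry()
        roi_cdr = pd.read_csv(self.out / "inverse" / "roi_cdr.tsv", sep="\t")
        tables, report = build_stat_report(roi_cdr, masks, self.config.stats.fdr_level)
        sdir = self.out / "stats"
        sdir.mkdir(exist_ok=True)
        outputs = []
        for t in tables:
            name = f"stats/stat_{t.component}_{t.family}.tsv"
            t.table.to_csv(self.out / name, sep="\t", index=False)
            outputs.append(name)
        _atomic_write_text(sdir / "report.md", report)
        outputs.append("stats/report.md")
        return outputs

    def _stage_report(self) -> list[str]:
        truth = json.loads((self.out / "study" / "truth.json").read_text())
        level = self.config.stats.fdr_level
        stat_files = sorted((self.out / "stats").glob("stat_*.tsv"))
        stat = pd.concat(
            [pd.read_csv(f, sep="\t") for f in stat_files], ignore_index=True
        )
        planted = truth.get("planted_effects", [])
        recovery = []
        for e in planted:
            hit = stat[(stat["roi"] == e["roi"]) & (stat["component"] == e["component"])]
            recovered = bool(
                not hit.empty
                and (hit["q"] < level).any()
                and (hit["mean_diff"] > 0).all()
            )
            recovery.append({"roi": e["roi"], "component": e["component"],
                             "recovered": recovered})
        reversed_sig = stat[(stat["q"] < level) & (stat["mean_diff"] < 0)]
        rdir = self.out / "report"
        rdir.mkdir(exist_ok=True)
        payload = {
            "fdr_level": level,
            "planted": recovery,
            "n_significant": int((stat["q"] < level).sum()),
            "n_significant_reversed": int(len(reversed_sig)),
        }
        _atomic_write_text(rdir / "recovery.json", json.dumps(payload, indent=1))
        lines = ["# Study summary", ""]
        for r in recovery:
            mark = "recovered" if r["recovered"] else "missed"
            lines.append(f"- planted {r['component']} effect in {r['roi']}: {mark}")
        lines.append(f"- significant ROIs total: {payload['n_significant']}")
        lines.append(
            f"- significant reversed-direction ROIs: {payload['n_significant_reversed']}"
        )
        _atomic_write_text(rdir / "summary.md", "\n".join(lines) + "\n")
        return ["report/recovery.json", "report/summary.md"]


def _jsonround(obj):
    """Canonicalize a params dict through JSON so cache comparison is
    independent of tuple/list distinctions."""
    return json.loads(json.dumps(obj))
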