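"""Config-driven orchestration of the three arms and per-residue synthesis.

A single YAML config enables any subset of the arms; :func:`run` executes
them, writes every artifact (CSV/JSON) plus a manifest, and is idempotent
for a fixed seed.  :func:`report` merges the per-residue classifications:
spin-label accessibility changes, HDX region classes and MD annotations are
juxtaposed, and residues where the arms disagree (one deprotected, the other
protected) are flagged as conflicts rather than resolved.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eseem as es
from . import hdx as hx
from . import mdstruct as md

__all__ = ["RunConfig", "run", "report", "load_config"]

log = logging.getLogger("statecompare")


class RunConfig(dict):
    """Validated run configuration (dict-like; see load_config)."""

    ARMS = ("eseem", "hdx", "md")

    @property
    def enabled_arms(self) -> list[str]:
        return [a for a in self.ARMS if a in self and self[a]]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(raw)
    if not cfg.enabled_arms:
        raise ValueError("config enables no analysis arm")
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "statecompare_out")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_trace_dir(spec) -> list:
    if isinstance(spec, (list, tuple)):
        paths = [str(p) for p in spec]
    else:
        p = Path(spec)
        if p.is_dir():
            paths = sorted(glob.glob(str(p / "*.dat")) + glob.glob(str(p / "*.csv")))
        else:
            paths = sorted(glob.glob(str(spec)))
    if not paths:
        raise FileNotFoundError(f"no trace files under {spec!r}")
    return [es.load_trace(p) for p in paths]


def _run_eseem(cfg: dict, out: Path) -> dict:
    method = cfg.get("method", "fit")
    reference = cfg.get("reference", "max")
    traces_a = _load_trace_dir(cfg["traces"] if "traces" in cfg else cfg["traces_a"])
    panel_a = es.panel_from_traces(traces_a, method=method, reference=reference)
    files = {}
    pa = out / "eseem_panel_a.csv"
    panel_a.write_csv(pa)
    files["panel_a"] = pa.name
    if cfg.get("traces_b"):
        traces_b = _load_trace_dir(cfg["traces_b"])
        panel_b = es.panel_from_traces(traces_b, method=method, reference=reference)
        pb = out / "eseem_panel_b.csv"
        panel_b.write_csv(pb)
        files["panel_b"] = pb.name
        comparison = es.compare_states(panel_a, panel_b)
        pc = out / "eseem_comparison.csv"
        comparison.to_csv(pc, index=False)
        files["comparison"] = pc.name
    return files


def _run_hdx(cfg: dict, out: Path) -> dict:
    table_a = hx.load_uptake_table(cfg["a"], protein_length=cfg.get("protein_length"))
    table_b = hx.load_uptake_table(cfg["b"], protein_length=cfg.get("protein_length"))
    alpha = float(cfg.get("alpha", 0.01))
    result = hx.differential_uptake(table_a, table_b, alpha=alpha,
                                    method=cfg.get("method", "summed"))
    mapped = hx.map_regions(result, protein_length=table_a.protein_length)
    files = {}
    fd = out / "hdx_differential.csv"
    result.write_csv(fd)
    files["differential"] = fd.name
    fr = out / "hdx_regions.csv"
    mapped["regions"].to_csv(fr, index=False)
    files["regions"] = fr.name
    fc = out / "hdx_residue_classes.csv"
    mapped["residue_classes"].to_csv(fc, index=False)
    files["residue_classes"] = fc.name
    fw = out / "hdx_woods.json"
    with open(fw, "w") as fh:
        json.dump({"alpha": alpha, "threshold": result.threshold,
                   "segments": mapped["woods_segments"]}, fh, indent=2)
    files["woods"] = fw.name
    cov = hx.coverage_stats(table_a, tuple(cfg.get("coverage_range", (1, table_a.protein_length))))
    fcov = out / "hdx_coverage.csv"
    pd.DataFrame([{"range_start": cov.residue_range[0], "range_end": cov.residue_range[1],
                   "coverage_percent": cov.coverage_percent,
                   "redundancy": cov.redundancy,
                   "n_uncovered": len(cov.uncovered)}]).to_csv(fcov, index=False)
    files["coverage"] = fcov.name
    return files


def _run_md(cfg: dict, out: Path) -> dict:
    system = md.load_system(cfg["structure"], cfg.get("trajectory"),
                            cfg.get("parameter_table"))
    tasks = cfg.get("tasks", {"thickness": {}})
    files = {}
    for task, opts in tasks.items():
        opts = opts or {}
        if task == "thickness":
            vals = md.membrane_thickness(system, opts.get("phosphate_selection"))
            df = pd.DataFrame({"frame": np.arange(len(vals)), "thickness_nm": vals})
        elif task == "tilt":
            vals = md.helix_tilt(system, tuple(opts["residue_range"]),
                                 segid=opts.get("segid"))
            df = pd.DataFrame({"frame": np.arange(len(vals)), "tilt_deg": vals})
        elif task == "rmsd":
            vals = md.rmsd_trajectory(system, ref_frame=int(opts.get("ref_frame", 0)))
            df = pd.DataFrame({"frame": np.arange(len(vals)), "rmsd_A": vals})
        elif task == "pore":
            prof = md.pore_profile(system, step=float(opts.get("step", 0.25)),
                                   z_range=tuple(opts["z_range"]) if "z_range" in opts else None)
            df = prof.to_frame()
        elif task == "density":
            prof = md.solvent_density_profile(
                system, cylinder_radius=float(opts.get("cylinder_radius", 8.0)))
            df = prof.to_frame()
        elif task == "sasa":
            vals = md.pocket_sasa(system, opts["pocket_residues"],
                                  probe=float(opts.get("probe", 1.4)))
            df = pd.DataFrame({"frame": np.arange(len(vals)), "sasa_A2": vals})
        else:
            raise ValueError(f"unknown md task {task!r}")
        path = out / f"md_{task}.csv"
        df.to_csv(path, index=False)
        files[task] = path.name
    return files


_ARM_RUNNERS = {"eseem": _run_eseem, "hdx": _run_hdx, "md": _run_md}


def run(config: RunConfig | dict | str) -> dict:
    """Execute every enabled arm; returns (and writes) the artifact manifest.

    Arm failures are recorded in the manifest's ``errors`` and do not stop
    the other arms; the manifest notes overall success.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif not isinstance(config, RunConfig):
        config = RunConfig(config)
    out = Path(config.get("out_dir", "statecompare_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(config.get("seed", 0)), "arms": {}, "errors": {},
                "out_dir": str(out)}
    for arm in config.enabled_arms:
        try:
            manifest["arms"][arm] = _ARM_RUNNERS[arm](config[arm], out)
        except Exception as exc:
            log.error("arm %s failed: %s", arm, exc)
            manifest["errors"][arm] = f"{type(exc).__name__}: {exc}"
    manifest["ok"] = not manifest["errors"]
    manifest["hashes"] = {
        fname: _sha256(out / fname)
        for files in manifest["arms"].values() for fname in files.values()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _residue_from_label(label: str) -> int | None:
    m = re.search(r"(\d+)", str(label))
    return int(m.group(1)) if m else None


def report(manifest: dict | str) -> dict:
    """Merge per-residue classifications across arms into a StateReport.

    Returns {'residues': DataFrame, 'md_summary': dict, 'conflicts': [...]};
    residues absent from every arm never appear.  The merge key is the
    residue number (ESEEM labels are parsed, HDX classes come from
    map_regions).
    """
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    out = Path(manifest["out_dir"])
    arms = manifest.get("arms", {})
    if not arms:
        raise ValueError("empty manifest: no arm artifacts to report on")

    per_residue: dict[int, dict] = {}
    if "eseem" in arms and "comparison" in arms["eseem"]:
        comp = pd.read_csv(out / arms["eseem"]["comparison"])
        for _, row in comp.iterrows():
            res = _residue_from_label(row["label"])
            if res is None:
                continue
            per_residue.setdefault(res, {})["eseem_class"] = row["class"]
            per_residue[res]["eseem_delta_pct"] = float(row["delta_pct"])
            per_residue[res]["eseem_label"] = row["label"]
    if "hdx" in arms and "residue_classes" in arms["hdx"]:
        classes = pd.read_csv(out / arms["hdx"]["residue_classes"])
        for _, row in classes.iterrows():
            if row["class"] == "not_significant":
                continue
            per_residue.setdefault(int(row["residue"]), {})["hdx_class"] = row["class"]

    rows, conflicts = [], []
    for res in sorted(per_residue):
        entry = per_residue[res]
        ec, hc = entry.get("eseem_class"), entry.get("hdx_class")
        concordant = None
        conflict = False
        if ec and hc:
            if ec == hc and ec != "no_change":
                concordant = f"concordant-{ec}"
            elif {ec, hc} == {"deprotected", "protected"}:
                conflict = True
                conflicts.append(res)
        rows.append({"residue": res, "eseem_label": entry.get("eseem_label", ""),
                     "eseem_class": ec or "", "hdx_class": hc or "",
                     "eseem_delta_pct": entry.get("eseem_delta_pct", float("nan")),
                     "consensus": concordant or "", "conflict": conflict})
    residues = pd.DataFrame(rows)

    md_summary = {}
    for task, fname in arms.get("md", {}).items():
        df = pd.read_csv(out / fname)
        num = df.select_dtypes("number")
        md_summary[task] = {c: float(num[c].mean()) for c in num.columns
                            if c != "frame"}

    rep = {"residues": residues, "md_summary": md_summary, "conflicts": conflicts,
           "seed": manifest.get("seed")}
    residues.to_csv(out / "report_residues.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump({"residues": residues.to_dict(orient="records"),
                   "md_summary": md_summary, "conflicts": conflicts,
                   "seed": manifest.get("seed")}, fh, indent=2)
    return rep
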