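"""End-to-end pipeline orchestration with a reproducibility manifest.

A run config (YAML/dict) lists stages with parameter blocks; each stage
writes its outputs, and the manifest records inputs, outputs, SHA-256
checksums, the seed and per-stage wall time.  Deterministic stages re-run
bit-identically from the same config; a stage refuses to reuse a cached
output whose checksum no longer matches the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

log = logging.getLogger("memfluct")

_SCHEMA = {
    "simulate": {"kind", "params", "out"},
    "height": {"movie", "optics", "out"},
    "fluctstats": {"height", "fbrs", "out"},
    "tension": {"height", "fbrs", "out", "fit"},
    "stats": {"table", "out", "response", "fixed"},
}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> None:
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValueError("config must contain a 'stages' list")
    for st in config["stages"]:
        kind = st.get("stage")
        if kind not in _SCHEMA:
            raise ValueError(f"unknown stage {kind!r}")
        unknown = set(st) - _SCHEMA[kind] - {"stage"}
        if unknown:
            raise ValueError(f"stage {kind}: unknown keys {sorted(unknown)}")


def check_cached(manifest: dict, path: str) -> bool:
    """True if ``path`` exists and matches the checksum recorded for it."""
    rec = manifest.get("outputs", {}).get(str(path))
    if rec is None or not Path(path).exists():
        return False
    ok = sha256_file(path) == rec
    if not ok:
        log.warning("checksum mismatch for %s; not reusing", path)
    return ok


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    from . import synthetic, irm, fluctuation, psd as psdmod, io as mio

    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "stages": [], "outputs": {}}

    for st in config["stages"]:
        kind = st["stage"]
        t0 = time.time()
        log.info("stage %s starting", kind)
        outputs = []
        if kind == "simulate":
            params = synthetic.MembraneSimParams(
                **{**st.get("params", {}), "seed": seed})
            movie = synthetic.simulate_membrane_patch(params)
            optics = synthetic.OpticsConfig()
            intensity = synthetic.render_irm_movie(movie, optics, seed=seed)
            hpath = out_dir / f"{st['out']}_height.tif"
            ipath = out_dir / f"{st['out']}_irm.tif"
            mio.write_height_tiff(hpath, movie)
            mio.write_intensity_tiff(ipath, intensity)
            gt = synthetic.GroundTruth(artifact=st["out"], values={
                "sigma_true": params.sigma_true,
                "gamma_true": params.gamma_true,
                "eta_eff": params.eta_eff, "active_A": params.active_A})
            gpath = out_dir / f"{st['out']}_truth.json"
            gt.to_json(gpath)
            outputs = [hpath, ipath, gpath]
        elif kind == "height":
            intensity = mio.read_tiff(out_dir / st["movie"])
            optics = synthetic.OpticsConfig(**st.get("optics", {}))
            cal = irm.Calibration(optics.intensity_offset,
                                  optics.intensity_amplitude,
                                  optics.wavelength, optics.refractive_index)
            movie = irm.height_movie_from_irm(
                intensity, cal, optics.pixel_size, 0.05)
            fbrs = irm.select_fbrs(intensity, cal,
                                   pixel_size_nm=optics.pixel_size)
            hpath = out_dir / f"{st['out']}_height.tif"
            fpath = out_dir / f"{st['out']}_fbrs.csv"
            mio.write_height_tiff(hpath, movie)
            mio.write_fbr_csv(fpath, fbrs)
            outputs = [hpath, fpath]
        elif kind == "fluctstats":
            import pandas as pd
            movie = mio.read_height_tiff(out_dir / st["height"])
            fdf = pd.read_csv(out_dir / st["fbrs"])
            fbrs = [irm.FBR(origin=(int(r.origin_row), int(r.origin_col)),
                            side_pixels=int(r.side_pixels))
                    for r in fdf.itertuples()]
            rows = fluctuation.fluctuation_summary(movie, fbrs)
            spath = out_dir / f"{st['out']}_fluctstats.csv"
            pd.DataFrame(rows).to_csv(spath, index=False)
            outputs = [spath]
        elif kind == "tension":
            import pandas as pd
            movie = mio.read_height_tiff(out_dir / st["height"])
            fdf = pd.read_csv(out_dir / st["fbrs"])
            fbrs = [irm.FBR(origin=(int(r.origin_row), int(r.origin_col)),
                            side_pixels=int(r.side_pixels))
                    for r in fdf.itertuples()]
            cfg = psdmod.FitConfig(**st.get("fit", {}))
            fits, _ = psdmod.map_mechanics(movie, fbrs, cfg)
            rows = [{"fbr": i, "sigma_N_per_m": f.sigma,
                     "sigma_pN_per_um": f.sigma_pN_per_um, "A": f.A,
                     "eta_eff": f.eta_eff, "gamma": f.gamma,
                     "r_squared": f.r_squared} for i, f in enumerate(fits)]
            tpath = out_dir / f"{st['out']}_tension.csv"
            pd.DataFrame(rows).to_csv(tpath, index=False)
            outputs = [tpath]
        elif kind == "stats":
            import pandas as pd
            from .stats import mann_whitney_bonferroni
            df = pd.read_csv(out_dir / st["table"])
            fixed = st.get("fixed", "phase")
            response = st.get("response", "sigma_pN_per_um")
            groups = {str(g): sub[response].to_numpy()
                      for g, sub in df.groupby(fixed)}
            results = mann_whitney_bonferroni(groups) if len(groups) > 1 \
                else []
            rpath = out_dir / f"{st['out']}_stats.csv"
            pd.DataFrame([r.__dict__ for r in results]).to_csv(
                rpath, index=False)
            outputs = [rpath]
        for p in outputs:
            manifest["outputs"][str(p)] = sha256_file(p)
        manifest["stages"].append({
            "stage": kind, "outputs": [str(p) for p in outputs],
            "wall_time_s": round(time.time() - t0, 3)})
        log.info("stage %s done in %.1fs", kind, time.time() - t0)

    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
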