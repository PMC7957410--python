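"""End-to-end orchestration: simulate -> cosinor -> fit -> select -> decompose.

All randomness flows from the single root seed in the RunConfig; per-stage
seeds are derived with numpy SeedSequence spawning and logged in the
manifest, so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .io import RunConfig, config_hash, save_config, write_cell_table, \
    write_json
from .models import fit_cosinor_per_gene, fit_model
from .selection import compare, leave_replicate_out, psis_loo
from .synth import simulate_dataset
from .variance import decompose, gene_params_from_fit

log = logging.getLogger("circaburst")

_STAGES = ("simulate", "cosinor", "fit", "loo", "cv", "decompose")


def _stage_seeds(root_seed: int) -> dict:
    seqs = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return {s: int(q.generate_state(1)[0] % (2 ** 31))
            for s, q in zip(_STAGES, seqs)}


def pipeline_run(config: RunConfig, table=None) -> Path:
    """Run the full analysis pipeline; returns the artifact directory.

    If ``table`` is None a synthetic dataset is generated under
    ``config.generator_model``; otherwise the provided CellTable is
    analysed.  Any stage failure raises with the stage name; artifacts
    written so far are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    save_config(config, outdir / "config.yaml")
    write_json({"seed": config.seed, "stage_seeds": seeds,
                "version": __version__,
                "config_hash": config_hash(config)},
               outdir / "manifest.json")

    stage = "simulate"
    try:
        if table is None:
            table = simulate_dataset(config.generator_model, config.params,
                                     config.design, seeds["simulate"])
        write_cell_table(table, outdir / "cells.tsv")

        stage = "cosinor"
        cosinor_fits = fit_cosinor_per_gene(table)
        write_json({g: f.to_dict() for g, f in cosinor_fits.items()},
                   outdir / "cosinor.json")

        stage = "fit"
        fits = {}
        m2 = None
        order = [m for m in ("M1", "M2", "M3", "M4") if m in config.models]
        if any(m in order for m in ("M3", "M4")) and "M2" not in order:
            order.insert(0, "M2")
        for k, mid in enumerate(order):
            kwargs = {"cosinor_fits": cosinor_fits}
            if mid in ("M3", "M4"):
                kwargs["m2"] = m2
            est = fit_model(table, mid, chains=config.chains,
                            draws=config.draws,
                            seed=seeds["fit"] + k, **kwargs)
            fits[mid] = est
            if mid == "M2":
                m2 = est
            write_json(est.summary().to_dict(orient="records"),
                       outdir / f"posterior_{mid}.json")
            est.summary().to_csv(outdir / f"posterior_{mid}.tsv",
                                 sep="\t", index=False)

        stage = "loo"
        loos = [psis_loo(est) for est in fits.values()]
        write_json({"comparison": compare(loos).to_dict(orient="records"),
                    "per_model": [r.to_dict() for r in loos]},
                   outdir / "loo.json")

        if config.run_cv:
            stage = "cv"
            cvs = []
            for k, (mid, est) in enumerate(fits.items()):
                def factory(seed, _mid=mid, _m2=m2):
                    kw = {"chains": config.chains, "draws": config.draws,
                          "random_state": seed}
                    if _mid in ("M3", "M4"):
                        kw["m2"] = _m2
                    from .models import MODEL_CLASSES
                    return MODEL_CLASSES[_mid](**kw)
                cvs.append(leave_replicate_out(
                    table, factory, S=config.cv_S, seed=seeds["cv"] + k))
            write_json({"comparison": compare(cvs).to_dict(orient="records"),
                        "per_model": [r.to_dict() for r in cvs]},
                       outdir / "cv.json")

        stage = "decompose"
        comp = {}
        areas = table["area"].to_numpy(dtype=float)
        times = np.unique(table["time_h"].to_numpy(dtype=float))
        for g, cf in cosinor_fits.items():
            if "M4" in fits:
                m4 = fits["M4"]
                fixed = (m4.m2.fixed_params() if m4.m2 is not None
                         else m4.fixed)
                gp = gene_params_from_fit(
                    cf, gamma=fixed[g]["gamma"], beta=fixed[g]["beta"],
                    mu=m4.posterior_mean_[f"mu_{g}"],
                    sigma=m4.posterior_mean_[f"sigma_{g}"], name=g)
            else:
                gp = config.params.gene(g)
            comp[g] = decompose(gp, areas, times,
                                seed=seeds["decompose"]).to_dict()
        write_json(comp, outdir / "variance.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
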