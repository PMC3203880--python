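"""End-to-end orchestration: simulate/load -> diversity -> neutrality ->
structure -> expansion dating -> divergence dating.

Each stage writes its results to files inside the output bundle so stages
can be inspected and re-run independently; a manifest records per-stage
status, seeds and runtimes.  A failed stage is logged, marked in the
manifest, and its dependents are skipped; the bundle is still written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .divergence import (
    DEFAULT_RATES,
    RateSet,
    abc_divergence_posterior,
    net_divergence_time,
)
from .errors import ConfigError
from .expansion import expansion_time, fit_sudden_expansion
from .neutrality import neutrality_result
from .seqio import (
    euclidean_site_distances,
    read_alignment,
    read_sample_table,
    write_pairwise_matrix,
)
from .simulate import SimConfig, inject_secondary_contact, simulate_history
from .structure import mantel_test, pairwise_phist, samova_scan
from .sumstats import (
    collapse_haplotypes,
    detect_secondary_contact,
    diversity_report,
    minimum_spanning_network,
    mismatch_distribution,
)

log = logging.getLogger("fragpop.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; serialized into the results bundle."""

    sim: SimConfig | None = None
    fasta: str | None = None
    samples_tsv: str | None = None
    locus: str = "ND2"
    mu_site_per_year: float = 5.7e-9
    generation_time: float = 2.0
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    samova_K: tuple[int, int] = (2, 4)
    samova_restarts: int = 20
    mantel_permutations: int = 10_000
    neutrality_reps: int = 1000
    abc_sims: int = 10_000
    abc_accept: float = 0.02
    mismatch_bootstrap: int = 100
    secondary_contact: str = "exclude"  # exclude | keep
    inject_sc: dict | None = None  # {"source":..., "target":..., "k": int}
    sc_min_steps: int = 5
    expansion_population: str | None = None
    divergence_pairs: list[tuple[str, str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and (self.fasta is None or self.samples_tsv is None):
            raise ConfigError("need either a simulation config or input paths")
        if self.secondary_contact not in ("exclude", "keep"):
            raise ConfigError("secondary_contact must be 'exclude' or 'keep'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if d.get("samova_K") is not None:
            d["samova_K"] = tuple(d["samova_K"])
        if d.get("divergence_pairs") is not None:
            d["divergence_pairs"] = [tuple(p) for p in d["divergence_pairs"]]
        return cls(**d)


def _stage(manifest, name, func, *deps):
    """Run one stage with timing and failure isolation."""
    for dep in deps:
        if manifest["stages"].get(dep, {}).get("status") != "ok":
            manifest["stages"][name] = {"status": "skipped",
                                        "reason": f"dependency {dep} failed"}
            log.warning("stage %s skipped (dependency %s)", name, dep)
            return None
    t0 = time.perf_counter()
    try:
        out = func()
    except Exception as exc:  # noqa: BLE001 - stage isolation is the point
        manifest["stages"][name] = {
            "status": "failed",
            "error": f"{type(exc).__name__}: {exc}",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.exception("stage %s failed", name)
        return None
    manifest["stages"][name] = {
        "status": "ok",
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("stage %s ok (%.2fs)", name,
             manifest["stages"][name]["seconds"])
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; return the manifest (also written to the bundle)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    sub_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": dict(
            zip(["simulate", "sumstats", "neutrality", "structure",
                 "expansion", "divergence", "inject", "spare"], sub_seed)
        ),
        "stages": {},
    }
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    state: dict = {}

    def stage_data():
        if config.sim is not None:
            sim = simulate_history(config.sim)
            if config.inject_sc:
                sim = inject_secondary_contact(
                    sim,
                    source=config.inject_sc["source"],
                    target=config.inject_sc["target"],
                    k=int(config.inject_sc["k"]),
                    seed=sub_seed[6],
                )
            sim.write(out)
            state["aln"] = sim.alignment
            state["samples"] = sim.samples
        else:
            state["aln"] = read_alignment(config.fasta, config.locus)
            state["samples"] = read_sample_table(config.samples_tsv)
            state["samples"].validate_against(state["aln"])

    _stage(manifest, "data", stage_data)

    exclude = config.secondary_contact == "exclude"

    def stage_sumstats():
        aln, samples = state["aln"], state["samples"]
        rep = diversity_report(aln, samples, exclude_transplanted=True)
        rep.to_csv(out / "diversity.tsv", sep="\t", index=False,
                   float_format="%.6g")
        ht = collapse_haplotypes(aln, samples,
                                 exclude_transplanted=exclude)
        edges = minimum_spanning_network(ht)
        pd.DataFrame(edges, columns=["hap_i", "hap_j", "steps"]).to_csv(
            out / "haplotype_network.tsv", sep="\t", index=False
        )
        ht_all = collapse_haplotypes(aln, samples, exclude_transplanted=False)
        flags = detect_secondary_contact(ht_all, min_steps=config.sc_min_steps)
        (out / "secondary_contact.json").write_text(
            json.dumps({"min_steps": config.sc_min_steps, "flagged": flags},
                       indent=2) + "\n"
        )
        state["report"] = rep

    _stage(manifest, "sumstats", stage_sumstats, "data")

    def stage_neutrality():
        aln, samples = state["aln"], state["samples"]
        rows = []
        for pop in samples.populations:
            try:
                r = neutrality_result(
                    aln, samples, pop, n_reps=config.neutrality_reps,
                    seed=sub_seed[2], exclude_transplanted=exclude,
                )
            except Exception as exc:  # population too small etc.
                log.warning("neutrality skipped for %s: %s", pop, exc)
                continue
            rows.append(dataclasses.asdict(r))
        df = pd.DataFrame(rows)
        df.to_csv(out / "neutrality.tsv", sep="\t", index=False,
                  float_format="%.6g")
        state["neutrality"] = df

    _stage(manifest, "neutrality", stage_neutrality, "data")

    def stage_structure():
        aln, samples = state["aln"], state["samples"]
        k_lo, k_hi = config.samova_K
        k_hi = min(k_hi, len(samples.sites))
        results, selected = samova_scan(
            aln, samples, range(k_lo, k_hi + 1),
            n_restarts=config.samova_restarts, seed=sub_seed[3],
            exclude_transplanted=exclude,
        )
        prof = pd.DataFrame(
            {"K": [r.K for r in results], "F_CT": [r.F_CT for r in results]}
        )
        prof.to_csv(out / "samova_profile.tsv", sep="\t", index=False,
                    float_format="%.6g")
        best = next(r for r in results if r.K == selected)
        pd.DataFrame(
            sorted(best.assignment.items()), columns=["site_id", "group"]
        ).to_csv(out / "samova_assignment.tsv", sep="\t", index=False)
        phist = pairwise_phist(aln, samples, exclude_transplanted=exclude)
        write_pairwise_matrix(phist, out / "phist.tsv")
        geo = euclidean_site_distances(samples, level="population")
        mt = mantel_test(
            geo.reorder(phist.labels),
            phist,
            n_perm=config.mantel_permutations,
            seed=sub_seed[3],
        )
        (out / "mantel.json").write_text(
            json.dumps({"r": mt.r, "p": mt.p, "n_perm": mt.n_perm},
                       indent=2) + "\n"
        )
        state["selected_K"] = selected

    _stage(manifest, "structure", stage_structure, "data")

    def stage_expansion():
        aln, samples = state["aln"], state["samples"]
        pop = config.expansion_population
        if pop is None:
            # default to the largest population, where expansion signal lives
            pop = samples.df["population"].value_counts().idxmax()
        md = mismatch_distribution(aln, samples, pop,
                                   exclude_transplanted=exclude)
        fit = fit_sudden_expansion(md, n_bootstrap=config.mismatch_bootstrap,
                                   seed=sub_seed[4])
        timing = expansion_time(fit.tau, config.mu_site_per_year,
                                state["aln"].length, config.generation_time)
        (out / "mismatch_fit.json").write_text(
            json.dumps(
                {
                    "population": pop,
                    "tau": fit.tau, "theta0": fit.theta0,
                    "theta1": fit.theta1, "ssd": fit.ssd,
                    "tau_ci95": fit.tau_ci,
                    "t_generations": timing.t_generations,
                    "T_years": timing.T_years,
                    "mismatch_counts": list(md.counts),
                },
                indent=2,
            ) + "\n"
        )

    _stage(manifest, "expansion", stage_expansion, "data")

    def stage_divergence():
        aln, samples = state["aln"], state["samples"]
        # U is the geometric mean over the markers actually analyzed; with
        # a single sequenced locus that is just its own calibrated rate
        if config.locus in config.rates:
            rates = RateSet(rates={config.locus: config.rates[config.locus]})
        else:
            rates = RateSet(rates=dict(config.rates))
        pairs = config.divergence_pairs
        if pairs is None:
            pops = [p for p in samples.populations]
            pairs = [(pops[0], p) for p in pops[1:]]
        rs = np.random.SeedSequence(sub_seed[5]).spawn(len(pairs))
        for (a, b), ss in zip(pairs, rs):
            try:
                post = abc_divergence_posterior(
                    aln, samples, a, b, rates,
                    n_sims=config.abc_sims, accept_frac=config.abc_accept,
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                    exclude_transplanted=exclude,
                )
                payload = {
                    "popA": a, "popB": b,
                    "t_mode": post.mode, "t_hpd95": list(post.hpd95),
                    "U": post.U,
                    "T_years_mode": post.T_years_mode,
                    "T_years_hpd95": list(post.T_years_hpd),
                    "acceptance_rate": post.acceptance_rate,
                    "priors": post.priors,
                    "T_years_net_divergence": net_divergence_time(
                        aln, samples, a, b, post.U,
                        exclude_transplanted=exclude,
                    ),
                }
            except Exception as exc:
                log.warning("divergence %s-%s failed: %s", a, b, exc)
                payload = {"popA": a, "popB": b,
                           "error": f"{type(exc).__name__}: {exc}"}
            (out / f"divergence_{a}_{b}.json").write_text(
                json.dumps(payload, indent=2) + "\n"
            )

    _stage(manifest, "divergence", stage_divergence, "data")

    manifest["ok"] = all(
        s.get("status") == "ok" for s in manifest["stages"].values()
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    log.removeHandler(fh)
    fh.close()
    return manifest
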