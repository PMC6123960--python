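"""Orchestration of the full stripe-evolution analysis.

One configuration drives every stage: coding enumeration, equal-rates vs
all-rates-different Mk fits and their likelihood-ratio test, marginal
ancestral states, stochastic mapping ensembles, the four-model MuSSE
comparison table, the PGLS regression battery, and the community
species-recognition randomization tests.  All randomness flows from one
master seed, split deterministically per stage; every output table records
the seeds and settings that produced it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (Community, SpeciesPool, CommunityRecognitionTest,
                        read_communities, read_pool)
from .mk import (MkModel, MorphCoding, aicc_table, enumerate_codings,
                 likelihood_ratio_test, read_coding)
from .morphometrics import compute_indexes, read_trait_table
from .musse import musse_model_table
from .pgls import pgls_battery
from .simmap import count_trajectory_transitions, summarize
from .tree import PhyloTree, parse_tree, reconcile

__all__ = ["RunConfig", "AnalysisReport", "validate_inputs", "run_full_analysis",
           "write_fixture"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    tree: str
    characters: str                 # character TSV (species, state)
    traits: str | None = None       # morphometric trait TSV
    pool: str | None = None        # species-pool TSV
    communities: str | None = None  # community TSV
    character: str = "stripes"      # "stripes" (k=4) or "ontogeny" (k=2)
    n_maps: int = 10_000
    n_random: int = 9_999
    sampling_fraction: float | None = None   # default n_tips/30 downstream
    seed: int = 0
    out: str = "stripevol_out"
    models: tuple[str, ...] = ("i", "ii", "iii", "iv")
    delta_aicc_support: float = 4.0
    transition_threshold: float = 0.5
    n_starts: int = 5
    prune_unmatched: bool = False

    @property
    def k(self) -> int:
        return 4 if self.character == "stripes" else 2

    def validate_paths(self) -> None:
        required = {"tree": self.tree, "characters": self.characters}
        optional = {"traits": self.traits, "pool": self.pool,
                    "communities": self.communities}
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


@dataclass
class AnalysisReport:
    """All tables of one run, plus the provenance block."""

    reconciliation: dict
    lrt_table: pd.DataFrame
    asr_tables: dict[str, pd.DataFrame]
    simmap_summaries: dict[str, dict]
    transition_branches: dict[str, int]
    musse_tables: dict[str, pd.DataFrame]
    musse_rate_summary: pd.DataFrame | None
    pgls_table: pd.DataFrame | None
    community_table: pd.DataFrame | None
    provenance: dict
    out_dir: Path | None = None


def _load_inputs(config: RunConfig):
    config.validate_paths()
    tree = parse_tree(Path(config.tree).read_text(),
                      "nexus" if config.tree.endswith((".nex", ".nexus")) else "newick")
    labels = ("A", "B", "C", "D") if config.k == 4 else ("no_loss", "loss")
    coding = read_coding(config.characters, k=config.k, labels=labels)
    return tree, coding


def validate_inputs(config: RunConfig) -> dict:
    """Reconciliation report: species mismatches, polymorphism, coding count.

    Purely diagnostic; no likelihood is computed.
    """
    tree, coding = _load_inputs(config)
    rep = reconcile(tree, coding.species)
    poly = coding.polymorphic_species
    out = {
        "n_tips": tree.n_tips,
        "tips_missing_traits": rep.tips_missing_traits,
        "traits_missing_tips": rep.traits_missing_tips,
        "n_matched": len(rep.matched),
        "polymorphic_species": sorted(poly),
        "n_coding_combinations": int(np.prod([len(coding.states[sp]) for sp in poly]))
        if poly else 1,
    }
    if config.traits:
        tdf = read_trait_table(config.traits)
        trep = reconcile(tree, list(tdf["species"]))
        out["trait_rows_missing_tips"] = trep.traits_missing_tips
    return out


def _coding_id(full: MorphCoding, resolved: MorphCoding) -> str:
    poly = sorted(full.polymorphic_species)
    if not poly:
        return "monomorphic"
    return "_".join(f"{sp}-{resolved.state_label(resolved.states[sp][0])}" for sp in poly)


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute every stage of the analysis over every coding combination."""
    t0 = time.time()
    tree, coding = _load_inputs(config)
    rep = validate_inputs(config)
    if rep["tips_missing_traits"]:
        if config.prune_unmatched:
            tree = tree.prune_to([t for t in tree.tip_labels
                                  if t not in set(rep["tips_missing_traits"])])
        else:
            raise ValueError(
                f"tips without character states: {rep['tips_missing_traits']}; "
                "supply states or set prune_unmatched"
            )
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("mk", "simmap", "musse", "community"),
        rng.integers(0, 2**31 - 1, size=4))}
    codings = enumerate_codings(coding)

    lrt_rows = []
    asr_tables: dict[str, pd.DataFrame] = {}
    simmap_summaries: dict[str, dict] = {}
    transition_branches: dict[str, int] = {}
    musse_tables: dict[str, pd.DataFrame] = {}
    rate_rows = []
    for cd in codings:
        cid = _coding_id(coding, cd)
        er = MkModel(tree, cd, MkModel.er_spec(cd.k)).fit(config.n_starts, seeds["mk"])
        ard = MkModel(tree, cd, MkModel.ard_spec(cd.k)).fit(config.n_starts, seeds["mk"])
        stat, df, p = likelihood_ratio_test(er, ard)
        best = ard if p < 0.05 else er
        lrt_rows.append({"coding": cid, "lnL_ER": er.llf, "lnL_ARD": ard.llf,
                         "LRT": stat, "df": df, "p": p,
                         "selected": "ARD" if best is ard else "ER"})
        asr_tables[cid] = best.ancestral_states()
        ens = best.simulate_histories(n_maps=config.n_maps, seed=seeds["simmap"])
        summ = summarize(ens)
        simmap_summaries[cid] = {
            "node_frequencies": summ.node_frequencies,
            "transition_counts": summ.transition_counts,
            "dwell_times": summ.dwell_times,
        }
        transition_branches[cid] = len(
            count_trajectory_transitions(summ, config.transition_threshold))
        table = musse_model_table(
            tree, cd, f=config.sampling_fraction, models=config.models,
            n_starts=config.n_starts, seed=seeds["musse"])
        musse_tables[cid] = table
        if cd.k == 4:
            from .musse import fit_musse

            best_iv = fit_musse(tree, cd, "iv", f=config.sampling_fraction,
                                n_starts=config.n_starts, seed=seeds["musse"])
            rate_rows.append({"coding": cid,
                              "q_AB": best_iv.q_rates[0],
                              "q_BC": best_iv.q_rates[1],
                              "q_CD": best_iv.q_rates[2]})
    lrt_table = pd.DataFrame(lrt_rows)
    rate_summary = None
    if coding.k == 4 and rate_rows:
        rdf = pd.DataFrame(rate_rows).set_index("coding")
        rate_summary = rdf.agg(["mean", "std"]).T

    pgls_table = None
    if config.traits:
        tdf = compute_indexes(read_trait_table(config.traits))
        pgls_table = pgls_battery(tree, tdf)

    community_table = None
    if config.pool and config.communities:
        pool = read_pool(config.pool)
        comms = read_communities(config.communities)
        rows = []
        for i, c in enumerate(comms):
            res = CommunityRecognitionTest(c, pool).run(
                n_random=config.n_random, seed=seeds["community"] + i)
            pl, pe, pg = res.proportions
            rows.append({"location": c.location, "n_species": c.richness,
                         "max_identical_pairs": res.observed,
                         "prop_less": pl, "prop_equal": pe, "prop_greater": pg,
                         "p": res.pvalue, "p_mc": res.mc_pvalue})
        community_table = pd.DataFrame(rows)

    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
    }
    report = AnalysisReport(
        reconciliation=rep, lrt_table=lrt_table, asr_tables=asr_tables,
        simmap_summaries=simmap_summaries, transition_branches=transition_branches,
        musse_tables=musse_tables, musse_rate_summary=rate_summary,
        pgls_table=pgls_table, community_table=community_table,
        provenance=provenance,
    )
    if config.out:
        report.out_dir = _write_report(report, Path(config.out))
    return report


def _write_report(report: AnalysisReport, out: Path) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    report.lrt_table.to_csv(out / "mk_lrt.tsv", sep="\t", index=False)
    for cid, df in report.asr_tables.items():
        df.to_csv(out / f"asr_{cid}.tsv", sep="\t")
    for cid, df in report.musse_tables.items():
        df.to_csv(out / f"musse_models_{cid}.tsv", sep="\t", index=False)
    if report.musse_rate_summary is not None:
        report.musse_rate_summary.to_csv(out / "musse_model_iv_rates.tsv", sep="\t")
    if report.pgls_table is not None:
        report.pgls_table.to_csv(out / "pgls.tsv", sep="\t", index=False)
    if report.community_table is not None:
        report.community_table.to_csv(out / "community_tests.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"coding": cid, "n_transition_branches": n}
        for cid, n in report.transition_branches.items()
    ]).to_csv(out / "simmap_transitions.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
    return out


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_fixture(fixture, outdir: str | Path) -> Path:
    """Write a synthetic fixture to the on-disk formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(fixture.tree.to_newick() + "\n")
    _write_coding(fixture.stripes, out / "stripes.tsv")
    _write_coding(fixture.ontogeny, out / "ontogeny.tsv")
    fixture.traits.to_csv(out / "traits.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"species": sp,
         "morphs": ",".join("ABCD"[m] for m in ms)}
        for sp, ms in fixture.pool.morphs.items()
    ]).to_csv(out / "pool.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"location": c.location, "species": ",".join(c.species)}
        for c in fixture.communities
    ]).to_csv(out / "communities.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(fixture.manifest, indent=2))
    return out


def _write_coding(coding: MorphCoding, path: Path) -> None:
    pd.DataFrame([
        {"species": sp,
         "state": ",".join(coding.state_label(s) for s in st)}
        for sp, st in coding.states.items()
    ]).to_csv(path, sep="\t", index=False)
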