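"""Replicated experiment grids over demography, dominance, recombination,
split time, mating system, and chromosome type.

The default profile is a desk-scale replica of the full study conditions:
an ancestral population of ``N_A = 500`` diploids on a 500 kb chromosome
with the human gamma DFE, to which a further rescaling constant ``c`` is
applied (sizes and times divided by c, selection and mutation multiplied,
recombination mapped through the Haldane-consistent transformation).  All
replicate seeds are derived deterministically from one root seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import ancestry, popstats
from .engine import (
    DemographicModel,
    MatingConfig,
    SimulationConfig,
    SimulationResult,
    run,
)
from .genome import GenomeStructure, generate_random_structure
from .selection import (
    ADDITIVE,
    ADDITIVE_TEXTBOOK,
    ARABIDOPSIS,
    HS_FUNCTION,
    HUMAN,
    RECESSIVE,
    DFEParams,
    DominanceModel,
    SpeciesPreset,
)

#: the recombination rates of the study grid (per bp per generation)
GRID_RATES = (1e-6, 1e-7, 1e-8, 1e-9)

_DOMINANCE_ALIASES = {
    "additive": DominanceModel(ADDITIVE),
    "recessive": DominanceModel(RECESSIVE),
    "hs": HUMAN.dominance,
    "hs_arabidopsis": ARABIDOPSIS.dominance,
    "additive_textbook": DominanceModel(ADDITIVE_TEXTBOOK),
}


def derive_seed(root: int, *path) -> int:
    """Deterministic child seed (< 2^31) from a root seed and a path."""
    import zlib

    key = [int(root)]
    for p in path:
        if isinstance(p, str):
            key.append(zlib.crc32(p.encode()) % (2**31))
        else:
            key.append(int(p) % (2**31))
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def resolve_dominance(dominance) -> DominanceModel:
    if isinstance(dominance, DominanceModel):
        return dominance
    try:
        return _DOMINANCE_ALIASES[dominance]
    except KeyError:
        raise ValueError(f"unknown dominance mode {dominance!r}") from None


def build_config(*, model: int = 0, dominance="additive", r: float = 1e-8,
                 N_A: int = 500, L: int = 500_000, c: float = 5.0,
                 preset: SpeciesPreset = HUMAN, mu: float | None = None,
                 dfe: DFEParams | None = None, seed: int = 0,
                 structure_seed: int | None = None,
                 structure: GenomeStructure | None = None,
                 neutral: bool = False, selfing: tuple[float, float] = (0.0, 0.0),
                 x_mode: bool = False, t_s: int | None = None,
                 burn_in: int | None = None, post_admixture: int | None = None,
                 admixture_fraction: float = 0.05, markers: bool = False,
                 track_neutral: bool = True,
                 record_every: int = 50, prune_every: int = 100,
                 ns_syn_ratio: float = 2.31) -> SimulationConfig:
    """Assemble a (still unscaled) run configuration for one grid cell."""
    if structure is None:
        structure = generate_random_structure(
            L, structure_seed if structure_seed is not None else seed, r=r)
    else:
        structure = structure.with_uniform_rate(r) if r is not None else structure
    demography = DemographicModel.preset(
        model, N_A, burn_in=burn_in, t_s=t_s, post_admixture=post_admixture,
        admixture_fraction=admixture_fraction)
    return SimulationConfig(
        structure=structure, demography=demography,
        dfe=dfe or preset.dfe, dominance=resolve_dominance(dominance),
        mu=mu if mu is not None else preset.mu, ns_syn_ratio=ns_syn_ratio,
        c=c, seed=seed, neutral=neutral, track_neutral=track_neutral,
        mating=MatingConfig(selfing_donor=selfing[0],
                            selfing_recipient=selfing[1], x_mode=x_mode),
        markers=markers, record_every=record_every, prune_every=prune_every)


def config_from_yaml(path) -> SimulationConfig:
    """Build a run configuration from a YAML mapping of ``build_config``
    keywords (plus optional ``preset: human|arabidopsis``)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "preset" in raw:
        from .selection import PRESETS

        raw["preset"] = PRESETS[raw["preset"]]
    if "selfing" in raw:
        raw["selfing"] = tuple(raw["selfing"])
    return build_config(**raw)


def _summary_row(result: SimulationResult) -> dict:
    ts = result.timeseries
    rec = ts[ts["pop"] == "recipient"]
    don = ts[ts["pop"] == "donor"]
    final = rec.iloc[-1]
    row = dict(p_I_final=float(final["p_I"]),
               mean_w_final=float(final["mean_w"]))
    snap = result.pre_pulse
    if snap is not None:
        row["w_R_pulse"] = snap.mean_w["recipient"]
        row["w_D_pulse"] = snap.mean_w["donor"]
        row["w_ratio_pulse"] = snap.mean_w["recipient"] / snap.mean_w["donor"]
    pulse_rows = rec[rec["gen_rel"] == result.scaled_config.demography.t_s]
    if len(pulse_rows):
        row["p_I_pulse"] = float(pulse_rows.iloc[0]["p_I"])
    row["mean_w_donor_final"] = float(don.iloc[-1]["mean_w"])
    return row


def run_replicates(n_reps: int, seed: int, *, label=(), shared_structure: bool = False,
                   collect_timeseries: bool = False,
                   collect_results: bool = False, **cell) -> pd.DataFrame:
    """Run ``n_reps`` seed-distinct replicates of one grid cell.

    ``label`` tags the replicate seed derivation so that distinct cells
    never share random streams; with ``shared_structure`` the chromosome
    structure seed depends only on the replicate index, so cells differing
    in, say, inheritance mode see identical structures.
    """
    rows = []
    ts_frames = []
    results = []
    for rep in range(n_reps):
        rep_seed = derive_seed(seed, *label, rep)
        struct_seed = (derive_seed(seed, "structure", rep) if shared_structure
                       else derive_seed(seed, *label, "structure", rep))
        result = run(build_config(seed=rep_seed, structure_seed=struct_seed,
                                  **cell))
        row = dict(rep=rep, seed=rep_seed, **_summary_row(result))
        rows.append(row)
        if collect_timeseries:
            ts = result.timeseries.copy()
            ts["rep"] = rep
            ts_frames.append(ts)
        if collect_results:
            results.append(result)
    df = pd.DataFrame(rows)
    if collect_timeseries:
        df.attrs["timeseries"] = pd.concat(ts_frames, ignore_index=True)
    if collect_results:
        df.attrs["results"] = results
    return df


def run_grid(models: Sequence[int] = (0, 1, 2, 3, 4),
             dominances: Sequence = ("additive", "recessive"),
             rates: Sequence[float] = GRID_RATES, n_reps: int = 50,
             seed: int = 0, **profile) -> pd.DataFrame:
    """The demography x dominance x recombination-rate grid."""
    frames = []
    for model in models:
        for dom in dominances:
            for r in rates:
                df = run_replicates(n_reps, seed,
                                    label=("grid", model, str(dom), repr(r)),
                                    model=model, dominance=dom, r=r, **profile)
                df.insert(0, "model", model)
                df.insert(1, "dominance", str(dom))
                df.insert(2, "r", r)
                frames.append(df)
    return pd.concat(frames, ignore_index=True)


def aggregate_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Replicate means and 25th-75th percentile bands per grid cell."""
    def agg(group):
        out = {}
        for col in ("p_I_final", "w_ratio_pulse"):
            if col in group:
                vals = group[col].dropna()
                out[f"{col}_mean"] = vals.mean()
                out[f"{col}_q25"] = vals.quantile(0.25)
                out[f"{col}_q75"] = vals.quantile(0.75)
        out["n_reps"] = len(group)
        return pd.Series(out)
    keys = [k for k in ("model", "dominance", "r") if k in df.columns]
    return df.groupby(keys).apply(agg, include_groups=False).reset_index()


def run_split_sweep(t_s_values: Sequence[int], models: Sequence[int] = (0, 4),
                    n_reps: int = 20, seed: int = 0, r: float = 1e-9,
                    dominance="recessive", **profile) -> pd.DataFrame:
    """Vary the split-to-admixture time; recessive fitness, low recombination.

    For each replicate, records F_ST at the pulse (all segregating
    non-marker variants), the private/shared variant partition, and the
    final introgressed-ancestry fraction.
    """
    rows = []
    for model in models:
        for t_s in t_s_values:
            for rep in range(n_reps):
                rep_seed = derive_seed(seed, "split", model, t_s, rep)
                result = run(build_config(model=model, dominance=dominance,
                                          r=r, t_s=t_s, seed=rep_seed,
                                          **profile))
                snap = result.pre_pulse
                fst = np.nan
                priv_d = priv_r = shared = 0
                if snap is not None:
                    try:
                        fst = popstats.fst_for_split_sweep(snap, result.table)
                    except ValueError:
                        fst = np.nan
                    priv_r, priv_d, shared = popstats.private_shared(
                        snap.hap_ids["recipient"], snap.hap_ids["donor"],
                        result.table)
                rows.append(dict(model=model, t_s=t_s, rep=rep,
                                 fst_pulse=fst, private_donor=priv_d,
                                 private_recipient=priv_r, shared=shared,
                                 **_summary_row(result)))
    return pd.DataFrame(rows)


def run_selfing_grid(selfing_values: Sequence[float] = (0.25, 0.5, 0.75),
                     n_reps: int = 20, seed: int = 0,
                     preset: SpeciesPreset = ARABIDOPSIS,
                     dominance=None, **profile) -> pd.DataFrame:
    """The seven-cell mating-system grid (Model 0, h(s) dominance).

    Cells: both populations outcrossing; the outcrosser as donor with a
    partially selfing recipient; the partial selfer as donor with an
    outcrossing recipient.
    """
    dominance = dominance if dominance is not None else preset.dominance
    cells = [(0.0, 0.0)]
    cells += [(0.0, sp) for sp in selfing_values]
    cells += [(sp, 0.0) for sp in selfing_values]
    rows = []
    for sd, sr in cells:
        df = run_replicates(n_reps, seed,
                            label=("selfing", repr(sd), repr(sr)),
                            model=0, dominance=dominance, preset=preset,
                            selfing=(sd, sr), **profile)
        df.insert(0, "selfing_donor", sd)
        df.insert(1, "selfing_recipient", sr)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def run_x_vs_autosome(models: Sequence[int] = (0, 2, 4),
                      dominances: Sequence = ("additive", "recessive", "hs"),
                      n_reps: int = 20, seed: int = 0, **profile) -> pd.DataFrame:
    """Matched autosomal / X-linked runs on identical chromosome structures.

    X runs use hemizygous males, no male recombination, and
    dosage-compensated fitness; autosomal runs differ only in inheritance
    and fitness mode, so the X-to-autosome contrast isolates the
    chromosome type.
    """
    frames = []
    for model in models:
        for dom in dominances:
            for x_mode, chrom in ((False, "autosome"), (True, "X")):
                df = run_replicates(n_reps, seed, shared_structure=True,
                                    label=("xva", model, str(dom), chrom),
                                    model=model, dominance=dom, x_mode=x_mode,
                                    **profile)
                df.insert(0, "model", model)
                df.insert(1, "dominance", str(dom))
                df.insert(2, "chromosome", chrom)
                frames.append(df)
    return pd.concat(frames, ignore_index=True)


def window_table(result: SimulationResult, size: int = 100_000) -> pd.DataFrame:
    """Per-window introgression / exon density / recombination covariates."""
    from .genome import make_windows

    windows = make_windows(result.scaled_config.structure, size)
    haps = [h for ind in result.populations["recipient"]
            for h in ind.haplotypes()]
    seg = ancestry.p_i_from_segments(haps, windows)
    out = pd.DataFrame(dict(
        window_start=[w.start for w in windows],
        window_end=[w.end for w in windows],
        p_I_segment=seg.p_I_by_window,
        exon_density=[w.exon_density for w in windows],
        mean_r=[w.mean_r for w in windows],
    ))
    if result.scaled_config.markers:
        mk = ancestry.p_i_from_markers(haps, result.table, windows)
        out["p_I_marker"] = mk.p_I_by_window
    return out


def correlations_table(window_tables, seed: int = 0) -> pd.DataFrame:
    """Spearman rank correlations (random tie-break) between window-level
    introgressed ancestry and each genomic covariate, pooled over
    replicates."""
    pooled = pd.concat(window_tables, ignore_index=True)
    rng = np.random.default_rng(derive_seed(seed, "correlations"))
    rows = []
    for covariate in ("mean_r", "exon_density"):
        try:
            rho, p = popstats.spearman_random_ties(
                pooled[covariate].to_numpy(),
                pooled["p_I_segment"].to_numpy(), rng)
        except ValueError:
            # fewer than three windows, or a constant covariate (e.g. a
            # uniform recombination map): correlation undefined
            rho, p = np.nan, np.nan
        rows.append(dict(covariate=covariate, statistic="p_I_segment",
                         rho=rho, p_value=p, n_windows=len(pooled)))
    return pd.DataFrame(rows)


def desert_table(result: SimulationResult, rep: int = 0) -> pd.DataFrame:
    """Introgression-desert intervals of the final recipient population."""
    haps = [h for ind in result.populations["recipient"]
            for h in ind.haplotypes()]
    d = ancestry.desert_lengths(haps, result.scaled_config.structure.length)
    return pd.DataFrame(dict(rep=rep,
                             start=d.intervals[:, 0] if d.intervals.size else [],
                             end=d.intervals[:, 1] if d.intervals.size else [],
                             length=d.lengths))


def save_state(result: SimulationResult, outdir) -> None:
    """Write the final per-haplotype state: mutations, ancestry tracts,
    and the substitution log."""
    import gzip
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tbl = result.table
    with gzip.open(outdir / "final_state.tsv.gz", "wt") as fh:
        fh.write("pop\tindividual\thaplotype\tmutation_id\tposition\ts\th\t"
                 "func_class\torigin_pop\torigin_gen\n")
        for pop_name, pop in result.populations.items():
            for i, ind in enumerate(pop):
                for k, hap in enumerate(ind.haplotypes()):
                    for m in hap.ids:
                        fh.write(f"{pop_name}\t{i}\t{k}\t{m}\t"
                                 f"{tbl.position[m]}\t{tbl.s[m]:.6g}\t"
                                 f"{tbl.h[m]:.6g}\t{tbl.func_class[m]}\t"
                                 f"{tbl.origin_pop[m]}\t{tbl.origin_gen[m]}\n")
    with gzip.open(outdir / "segments.tsv.gz", "wt") as fh:
        fh.write("pop\tindividual\thaplotype\tstart\tend\torigin\n")
        for pop_name, pop in result.populations.items():
            for i, ind in enumerate(pop):
                for k, hap in enumerate(ind.haplotypes()):
                    start = 0
                    for end, orig in zip(hap.anc_ends, hap.anc_orig):
                        fh.write(f"{pop_name}\t{i}\t{k}\t{start}\t{end}\t"
                                 f"{orig}\n")
                        start = int(end)
    with open(outdir / "substitutions.tsv", "w") as fh:
        fh.write("mutation_id\tgeneration\ts\tposition\n")
        for m, gen in result.substitutions:
            fh.write(f"{m}\t{gen}\t{tbl.s[m]:.6g}\t{tbl.position[m]}\n")
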