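"""End-to-end orchestration: data -> diversity tables -> outlier scan ->
HKA/mlHKA -> MK-PRF -> TSV reports, with deterministic named seeding.

All randomness flows from one top-level seed via named substreams per stage,
so any stage can be re-run independently and reproducibly.  Reports are plain
TSV plus a plain-text run manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import is_defined
from .hka import PolyDivTable, hka_parametric_p, hka_test, mlhka_scan
from .mkprf import build_mk_table, mk_tables_to_frame, run_mkprf
from .outlier_scan import calibrate_null, flag_outliers, pi_ts_test
from .popstats import diversity_summary, hudson_fst, summary_table
from .seqdata import exclude_indels, polarize, read_locus
from .synthdata import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full run (synthetic or file-based input)."""

    outdir: str = "popgenscan_run"
    seed: int = 1
    # either a generator config (synthetic mode) ...
    generator: GeneratorConfig | None = None
    # ... or a directory of <locus>.fasta / .meta.tsv / .exons.tsv files
    input_dir: str | None = None
    candidate_loci: tuple[str, ...] = ()
    reference_loci: tuple[str, ...] = ()
    alpha: float = 0.05
    reps_outlier: int = 10_000
    reps_pi_ts: int = 10_000
    reps_hka: int = 10_000
    mlhka_T: float = 15.0
    mkprf_cycles: int = 100_000
    mkprf_burn_in: int = 1_000
    mkprf_thin: int = 10
    mkprf_tau: float = 15.0
    run_fst: bool = True
    fst_permutations: int = 10_000

    def validate(self, loci: list[str] | None = None) -> None:
        overlap = set(self.candidate_loci) & set(self.reference_loci)
        if overlap:
            raise ValueError(f"candidate and reference sets overlap: {sorted(overlap)}")
        if self.generator is None and self.input_dir is None:
            raise ValueError("either a generator config or an input_dir is required")
        if not self.reference_loci and self.generator is None:
            raise ValueError("no reference loci configured")
        if self.generator is not None and self.generator.n_reference_loci == 0:
            raise ValueError("no reference loci configured")
        if loci is not None:
            missing = (set(self.candidate_loci) | set(self.reference_loci)) - set(loci)
            if missing:
                raise ValueError(f"configured loci not found in input: {sorted(missing)}")


def _load_alignments(config: RunConfig):
    if config.generator is not None:
        ds = generate_dataset(config.generator, seed=config.seed)
        cand = list(ds.truth.loc[ds.truth["locus_class"] == "candidate", "locus_id"])
        ref = list(ds.truth.loc[ds.truth["locus_class"] == "reference", "locus_id"])
        return ds.alignments, tuple(cand), tuple(ref), ds.truth
    indir = Path(config.input_dir)
    alignments = []
    for locus in list(config.candidate_loci) + list(config.reference_loci):
        alignments.append(read_locus(indir / f"{locus}.fasta",
                                     indir / f"{locus}.meta.tsv",
                                     indir / f"{locus}.exons.tsv",
                                     locus_id=locus))
    return alignments, tuple(config.candidate_loci), tuple(config.reference_loci), None


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to config.outdir.

    Emits: diversity.tsv, fst.tsv, outliers.tsv, pi_ts.tsv, hka.tsv,
    mlhka.tsv, mkprf.tsv and manifest.txt.  A stage failure halts the run
    with the stage name; earlier outputs are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    reports: dict[str, pd.DataFrame] = {}
    t0 = time.time()

    config.validate()
    stage = "load"
    try:
        alignments, candidates, references, truth = _load_alignments(config)
        config.validate(loci=[a.locus_id for a in alignments])
        classes = {a.locus_id: exclude_indels(a) for a in alignments}
        species = alignments[0].species_labels
    except Exception as e:  # noqa: BLE001 - report the failing stage
        raise StageError(stage, e) from e

    def _write(name: str, df: pd.DataFrame):
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")
        reports[name] = df

    # ---- diversity ----------------------------------------------------
    stage = "diversity"
    try:
        rows = []
        for aln in alignments:
            cls = classes[aln.locus_id]
            for sp in aln.species_labels:
                s = diversity_summary(aln, cls, sp)
                rows.append({**vars(s),
                             "locus_class": ("candidate" if aln.locus_id in candidates
                                             else "reference"),
                             "silent_sites": cls.effective_sites("silent"),
                             "S_sil": _silent_S(aln, cls, sp),
                             "div_sil": _silent_div(aln, cls, sp)})
        diversity = pd.DataFrame(rows)
        _write("diversity", diversity)
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- FST ----------------------------------------------------------
    stage = "fst"
    try:
        rows = []
        if config.run_fst:
            for aln in alignments:
                for sp in aln.species_labels:
                    try:
                        r = hudson_fst(aln, classes[aln.locus_id], species=sp,
                                       n_perm=config.fst_permutations,
                                       seed=config.seed)
                    except ValueError as err:
                        warnings_log.append(f"fst {aln.locus_id}/{sp}: {err}")
                        continue
                    rows.append(vars(r))
        _write("fst", pd.DataFrame(rows))
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- outlier scan --------------------------------------------------
    stage = "outlier_scan"
    try:
        out_rows = []
        for sp in species:
            ref = diversity[(diversity["species"] == sp)
                            & (diversity["locus_class"] == "reference")]
            calib = pd.DataFrame({
                "theta_w": ref["S_sil"] / (ref["silent_sites"]
                                           * ref["n"].map(_a_of)),
                "sites": ref["silent_sites"]})
            n_chrom = int(ref["n"].iloc[0])
            null = calibrate_null(calib, n_chrom, reps=config.reps_outlier,
                                  seed=config.seed, species=sp)
            cand = diversity[(diversity["species"] == sp)
                             & (diversity["locus_class"] == "candidate")]
            cand_pts = pd.DataFrame({
                "locus_id": cand["locus_id"],
                "pi_sil": cand["pi_sil"],
                "tajima_d": cand["tajima_d"]})
            rep = flag_outliers(cand_pts, null, alpha=config.alpha)
            rep.insert(0, "species", sp)
            out_rows.append(rep)
        _write("outliers", pd.concat(out_rows, ignore_index=True))
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- pi_T-S --------------------------------------------------------
    stage = "pi_ts"
    try:
        rows = []
        for aln in alignments:
            if aln.locus_id not in candidates or len(aln.species_labels) != 2:
                continue
            r = pi_ts_test(aln, classes[aln.locus_id], reps=config.reps_pi_ts,
                           seed=config.seed, alpha=config.alpha)
            rows.append(vars(r))
        _write("pi_ts", pd.DataFrame(rows))
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- HKA / mlHKA ---------------------------------------------------
    stage = "hka"
    try:
        hka_rows, ml_rows = [], []
        for sp in species:
            table = _poly_div_table(diversity, sp, list(candidates))
            res = hka_test(table)
            p_sim = hka_parametric_p(table, reps=config.reps_hka,
                                     seed=config.seed, result=res)
            hka_rows.append({"species": sp, "deviation": res.deviation_sum,
                             "df": res.df, "p_chi": res.p_chi, "p_sim": p_sim,
                             "T_hat": res.T_hat, "boundary": res.boundary})
            full = _poly_div_table(diversity, sp,
                                   list(candidates) + list(references))
            ml = mlhka_scan(full, list(candidates), T=config.mlhka_T)
            ml.insert(0, "species", sp)
            ml_rows.append(ml)
        _write("hka", pd.DataFrame(hka_rows))
        _write("mlhka", pd.concat(ml_rows, ignore_index=True))
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- MK-PRF --------------------------------------------------------
    stage = "mkprf"
    try:
        prf_rows = []
        for sp in species:
            tables = []
            for aln in alignments:
                pol = polarize(aln, classes[aln.locus_id])
                n_sp = int(aln.species_rows(sp).sum())
                cls_label = ("candidate" if aln.locus_id in candidates
                             else "reference")
                tables.append(build_mk_table(pol, sp, n_sp, cls_label))
            post = run_mkprf(tables, cycles=config.mkprf_cycles,
                             burn_in=config.mkprf_burn_in,
                             thin=config.mkprf_thin, seed=config.seed,
                             tau=config.mkprf_tau)
            s = post.summary.copy()
            s.insert(0, "species", sp)
            s["ci_excludes_0"] = (s["q2.5"] > 0) | (s["q97.5"] < 0)
            prf_rows.append(s)
            mk_tables_to_frame(tables).to_csv(
                outdir / f"mk_tables_{sp}.tsv", sep="\t", index=False)
        _write("mkprf", pd.concat(prf_rows, ignore_index=True))
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- manifest ------------------------------------------------------
    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"popgenscan {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"elapsed_s: {time.time() - t0:.1f}\n")
        for k, v in vars(config).items():
            fh.write(f"config.{k}: {v}\n")
        for w in warnings_log:
            fh.write(f"warning: {w}\n")
    return reports


def _a_of(n):
    from ._util import harmonic
    return harmonic(int(n))


def _silent_S(aln, cls, sp):
    from .popstats import segregating_sites
    return segregating_sites(aln, cls, "silent", aln.species_rows(sp))


def _silent_div(aln, cls, sp):
    from .popstats import divergence_to_outgroup
    return divergence_to_outgroup(aln, cls, "silent", aln.species_rows(sp))


def _poly_div_table(diversity: pd.DataFrame, species: str,
                    loci: list[str]) -> PolyDivTable:
    """Silent-site (S, D, L, n) table for the HKA family of tests."""
    sub = diversity[(diversity["species"] == species)
                    & diversity["locus_id"].isin(loci)]
    sub = sub.set_index("locus_id").loc[loci].reset_index()
    return PolyDivTable(pd.DataFrame({
        "locus": sub["locus_id"],
        "S": sub["S_sil"].astype(int),
        "D": np.rint(sub["div_sil"] * sub["silent_sites"]).astype(int),
        "L": sub["silent_sites"],
        "n": sub["n"].astype(int)}))
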