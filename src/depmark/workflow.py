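"""Orchestration of the two end-to-end analyses.

``mouse_discovery`` runs, in memory: optional outlier exclusion ->
responder/nonresponder relabeling -> quantile normalization per tissue ->
the four group contrasts -> SAM on (NS-FLX + S-FLX-R) vs (S-C + S-FLX-NR) ->
reversal and stress-specific filters per tissue -> RRHO per tissue pair with
concordant/discordant gene extraction -> cross-tissue candidate table ->
optional over-representation.  ``human_validation`` runs: replicate
aggregation -> low-expression exclusion -> 2^-ddCt against the control
calibrator -> per-gene trait/state/prediction statistics.

File-based wrappers (:func:`run_mouse_discovery`, :func:`run_human_validation`)
read a :class:`PipelineConfig`, write every artifact as TSV/CSV/JSON, and
leave a manifest describing inputs, thresholds and seeds, sufficient to rerun
any stage in isolation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biomarkers import biomarker_verdicts
from .datatypes import ExpressionMatrix
from .diffexpr import contrast, kept_genes, reversal_filter, sam_select, stress_filter
from .errors import ConfigurationError, DataError
from .io import (
    read_expression_tsv, read_gene_list, write_expression_tsv, write_gene_list,
    write_json,
)
from .phenotype import classify_response, exclude_outlier_samples
from .preprocess import quantile_normalize
from .qpcr import (
    aggregate_ct, assign_reference_strata, delta_delta_ct, low_expression_filter,
)
from .rrho import default_step, overlap_genes, rrho_map, rrho_summary, signed_rank
from .selection import cross_tissue_candidates, ora_enrichment

TISSUE_PAIRS = (("ACC", "DG"), ("blood", "DG"), ("blood", "ACC"))


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for the file-based pipeline runs."""

    # mouse inputs
    matrix_paths: dict = field(default_factory=dict)        # tissue -> matrix TSV
    sample_sheet_paths: dict = field(default_factory=dict)  # tissue -> sheet CSV
    behavior_path: str | None = None
    prior_list_path: str | None = None
    gene_sets_path: str | None = None
    # human inputs
    ct_path: str | None = None
    clinical_path: str | None = None
    # thresholds
    reversal_p: float = 0.05
    stress_p: float = 0.01
    stress_fc: float = 1.2
    sam_fdr: float = 0.01
    sam_n_perm: int = 200
    rrho_step: int | None = None
    responder_cutoff: float = 2.0
    ct_max: float = 35.0
    min_fraction_detected: float = 0.8
    max_ct_spread: float = 0.5
    reference_genes: tuple = ("CRYL1", "SV2A")
    reference_boundary: float = 30.0
    calibrator_group: str = "control"
    exclude_samples: list = field(default_factory=list)
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        for name, lo, hi in (
            ("reversal_p", 0, 1), ("stress_p", 0, 1), ("sam_fdr", 0, 1),
            ("min_fraction_detected", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigurationError(f"{name} must lie in ({lo}, {hi}], got {v}")
        if self.stress_fc <= 1:
            raise ConfigurationError(f"stress_fc must exceed 1, got {self.stress_fc}")
        if self.rrho_step is not None and self.rrho_step < 1:
            raise ConfigurationError("rrho_step must be >= 1")

    # -- serialization (round-trips losslessly) --------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["reference_genes"] = list(d["reference_genes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["reference_genes"] = tuple(d.get("reference_genes", ("CRYL1", "SV2A")))
        return cls(**d)


# ---------------------------------------------------------------------------
# mouse discovery (in memory)
# ---------------------------------------------------------------------------

@dataclass
class MouseDiscoveryResult:
    candidates: pd.DataFrame
    venn: dict
    contrasts: dict          # tissue -> {name -> ContrastTable}
    reversal: dict           # tissue -> filter table
    stress_specific: dict    # tissue -> filter table
    sam: object
    rrho_maps: dict          # (tissueA, tissueB) -> {contrast -> RRHOMap}
    rrho_genes: dict         # (tissueA, tissueB) -> {mode -> [genes]}
    ora: pd.DataFrame | None
    manifest: dict


def mouse_discovery(
    matrices: dict[str, ExpressionMatrix],
    behavior: pd.DataFrame,
    prior_human: list[str] | None = None,
    gene_sets: dict | None = None,
    config: PipelineConfig | None = None,
) -> MouseDiscoveryResult:
    """Run the full mouse discovery analysis in memory."""
    config = config or PipelineConfig()
    config.validate()
    stage = "setup"
    try:
        stage = "exclude_outliers"
        if config.exclude_samples:
            matrices = {
                t: exclude_outlier_samples(m, list(config.exclude_samples))
                for t, m in matrices.items()
            }
        stage = "classify_response"
        relabeled = classify_response(behavior, cutoff=config.responder_cutoff)
        label_map = relabeled.set_index("mouse")["group"]
        matrices = {t: m.with_groups(label_map) for t, m in matrices.items()}

        stage = "quantile_normalize"
        matrices = {t: quantile_normalize(m) for t, m in matrices.items()}

        stage = "contrasts"
        contrasts: dict[str, dict[str, pd.DataFrame]] = {}
        for tissue, m in matrices.items():
            contrasts[tissue] = {
                "stress": contrast(m, "S-C", "NS-C"),
                "recovery": contrast(m, "S-FLX-R", "S-C"),
                "flx_only": contrast(m, "NS-FLX", "NS-C"),
            }

        stage = "sam_select"
        blood = matrices["blood"]
        sam_groups = blood.samples["group"]
        sam_labels = sam_groups.map(
            lambda g: "treated_recovered" if g in ("NS-FLX", "S-FLX-R")
            else ("stressed_untreated" if g in ("S-C", "S-FLX-NR") else None)
        ).dropna()
        sam = sam_select(
            blood.values[sam_labels.index], sam_labels,
            target_fdr=config.sam_fdr, n_perm=config.sam_n_perm, seed=config.seed,
        )

        stage = "filters"
        reversal = {
            t: reversal_filter(c["stress"], c["recovery"], c["flx_only"],
                               p_thresh=config.reversal_p)
            for t, c in contrasts.items()
        }
        stress_specific = {
            t: stress_filter(c["stress"], p_thresh=config.stress_p,
                             fc_thresh=config.stress_fc)
            for t, c in contrasts.items()
        }

        stage = "rrho"
        rrho_maps: dict = {}
        rrho_gene_lists: dict = {}
        for ta, tb in TISSUE_PAIRS:
            if ta not in contrasts or tb not in contrasts:
                continue
            common = contrasts[ta]["stress"].index.intersection(
                contrasts[tb]["stress"].index)
            step = config.rrho_step or default_step(len(common))
            rrho_maps[(ta, tb)] = {}
            rrho_gene_lists[(ta, tb)] = {}
            for cname in ("stress", "recovery"):
                la = signed_rank(contrasts[ta][cname].loc[common])
                lb = signed_rank(contrasts[tb][cname].loc[common])
                m = rrho_map(la, lb, step=step)
                rrho_maps[(ta, tb)][cname] = m
                if cname == "stress":
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rrho_gene_lists[(ta, tb)] = {
                            mode: overlap_genes(m, la, lb, mode)
                            for mode in ("concordant_up", "concordant_down",
                                         "discordant")
                        }

        stage = "cross_tissue_candidates"
        concordant: list[str] = []
        for pair in (("blood", "DG"), ("blood", "ACC")):
            lists = rrho_gene_lists.get(pair, {})
            concordant.extend(lists.get("concordant_up", []))
            concordant.extend(lists.get("concordant_down", []))
        discordant = {
            "DG": rrho_gene_lists.get(("blood", "DG"), {}).get("discordant", []),
            "ACC": rrho_gene_lists.get(("blood", "ACC"), {}).get("discordant", []),
        }
        if prior_human is None:
            warnings.warn("prior human list absent; prior_human_hit all false",
                          stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidates, venn = cross_tissue_candidates(
                reversal_lists=reversal,
                sam_genes=sam.selected,
                rrho_concordant=sorted(set(concordant)),
                rrho_discordant=discordant,
                stress_specific=kept_genes(stress_specific.get("blood",
                                           next(iter(stress_specific.values())))),
                prior_human=prior_human,
            )

        stage = "ora_enrichment"
        ora = None
        if gene_sets:
            background = contrasts["blood"]["stress"].index.tolist()
            top = [g for g in candidates.index if g in set(background)]
            if top:
                ora = ora_enrichment(top, gene_sets, background)
    except (DataError, ConfigurationError) as err:
        raise type(err)(f"stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "reversal_p": config.reversal_p, "stress_p": config.stress_p,
            "stress_fc": config.stress_fc, "sam_fdr": config.sam_fdr,
            "sam_n_perm": config.sam_n_perm, "rrho_step": config.rrho_step,
            "responder_cutoff": config.responder_cutoff,
        },
        "excluded_samples": list(config.exclude_samples),
        "group_sizes": {
            t: m.samples["group"].value_counts().to_dict() for t, m in matrices.items()
        },
        "contrasts": {t: sorted(c) for t, c in contrasts.items()},
        "sam_contrast": "(NS-FLX + S-FLX-R) vs (S-C + S-FLX-NR)",
        "rrho_pairs": [list(p) for p in rrho_maps],
        "n_candidates": int(len(candidates)),
        "multiplicity_control": "none (per-gene threshold filters)",
    }
    return MouseDiscoveryResult(
        candidates=candidates, venn=venn, contrasts=contrasts, reversal=reversal,
        stress_specific=stress_specific, sam=sam, rrho_maps=rrho_maps,
        rrho_genes=rrho_gene_lists, ora=ora, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# human validation (in memory)
# ---------------------------------------------------------------------------

@dataclass
class HumanValidationResult:
    verdicts: pd.DataFrame
    rq: pd.DataFrame
    excluded_low_expression: list
    qc: pd.DataFrame
    manifest: dict


def human_validation(
    ct_table: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> HumanValidationResult:
    """Run the human-cohort validation analysis in memory.

    Genes failing the low-expression gate still appear in the verdict table
    with call ``excluded_low_expression``.
    """
    config = config or PipelineConfig()
    config.validate()
    refs = tuple(config.reference_genes)

    mean_ct = aggregate_ct(ct_table, max_spread=config.max_ct_spread)
    non_ref = mean_ct.loc[~mean_ct["gene"].isin(refs)]
    retained, report = low_expression_filter(
        non_ref, ct_max=config.ct_max,
        min_fraction_detected=config.min_fraction_detected,
    )
    excluded = [g for g in report.index if g not in set(retained)]

    strata = assign_reference_strata(mean_ct, references=refs,
                                     boundary=config.reference_boundary)
    rq_parts = []
    for ref in refs:
        genes = [g for g in retained if strata.get(g) == ref]
        if not genes:
            continue
        sub = mean_ct.loc[mean_ct["gene"].isin(genes + [ref])]
        rq_parts.append(
            delta_delta_ct(sub, reference_gene=ref,
                           calibrator=config.calibrator_group)
        )
    if not rq_parts:
        raise DataError("no gene left after low-expression filtering")
    rq = pd.concat(rq_parts, ignore_index=True)

    verdicts = biomarker_verdicts(rq, clinical)
    if excluded:
        attrs = verdicts.attrs
        verdicts = verdicts.reindex(verdicts.index.union(excluded))
        verdicts.loc[excluded, ["trait_call", "state_call", "pred_call"]] = \
            "excluded_low_expression"
        verdicts.attrs = attrs
    verdicts = verdicts.sort_index()

    manifest = {
        "version": __version__,
        "reference_genes": list(refs),
        "reference_boundary": config.reference_boundary,
        "calibrator": config.calibrator_group,
        "ct_max": config.ct_max,
        "min_fraction_detected": config.min_fraction_detected,
        "excluded_low_expression": excluded,
        "n_genes": int(len(verdicts)),
        "expr_scale": verdicts.attrs.get("expr_scale", "rq"),
    }
    return HumanValidationResult(
        verdicts=verdicts, rq=rq, excluded_low_expression=excluded,
        qc=report, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# file-based wrappers
# ---------------------------------------------------------------------------

def run_mouse_discovery(config: PipelineConfig) -> MouseDiscoveryResult:
    """Read mouse inputs from ``config`` paths, run, and write all artifacts."""
    from .io import read_gmt  # local import; optional input

    matrices = {
        t: read_expression_tsv(config.matrix_paths[t], config.sample_sheet_paths[t])
        for t in config.matrix_paths
    }
    behavior = pd.read_csv(config.behavior_path)
    prior = None
    if config.prior_list_path and Path(config.prior_list_path).exists():
        prior = read_gene_list(config.prior_list_path)
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None

    result = mouse_discovery(matrices, behavior, prior_human=prior,
                             gene_sets=gene_sets, config=config)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.candidates.to_csv(out / "candidates.tsv", sep="\t")
    write_json(result.venn, out / "venn_counts.json")
    for tissue, tables in result.contrasts.items():
        for name, table in tables.items():
            table.to_csv(out / f"contrast_{tissue}_{name}.tsv", sep="\t")
        result.reversal[tissue].to_csv(out / f"reversal_{tissue}.tsv", sep="\t")
        result.stress_specific[tissue].to_csv(out / f"stress_specific_{tissue}.tsv",
                                              sep="\t")
    write_gene_list(result.sam.selected, out / "sam_selected.txt")
    for (ta, tb), maps in result.rrho_maps.items():
        for cname, m in maps.items():
            m.to_frame().to_csv(out / f"rrho_{ta}_{tb}_{cname}.tsv", sep="\t")
            s = rrho_summary(m)
            write_json(
                {"step": m.step, "n_genes": m.n_genes, "mode": m.mode,
                 "max_neg_log10_p": s.max_neg_log_p, "argmax": list(s.argmax),
                 "quadrant": s.quadrant},
                out / f"rrho_{ta}_{tb}_{cname}.json",
            )
    for (ta, tb), lists in result.rrho_genes.items():
        for mode, genes in lists.items():
            write_gene_list(genes, out / f"rrho_genes_{ta}_{tb}_{mode}.txt")
    if result.ora is not None:
        result.ora.to_csv(out / "ora.tsv", sep="\t")
    write_json(result.manifest, out / "manifest_mouse.json")
    config.to_yaml(out / "config.yaml")
    return result


def run_human_validation(config: PipelineConfig) -> HumanValidationResult:
    """Read human inputs from ``config`` paths, run, and write all artifacts."""
    ct_table = pd.read_csv(config.ct_path)
    clinical = pd.read_csv(config.clinical_path)
    result = human_validation(ct_table, clinical, config=config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.verdicts.to_csv(out / "verdicts.tsv", sep="\t")
    result.rq.to_csv(out / "rq.tsv", sep="\t", index=False)
    result.qc.to_csv(out / "qpcr_qc.tsv", sep="\t")
    write_json(result.manifest, out / "manifest_human.json")
    return result


def simulate_to_files(outdir, mouse_config=None, human_config=None) -> dict:
    """Generate both synthetic datasets and write them as pipeline inputs.

    Returns a dict of the paths written (suitable for building a
    :class:`PipelineConfig`).
    """
    from .io import write_truth
    from .simulate import simulate_human_cohort, simulate_mouse_study

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"matrix_paths": {}, "sample_sheet_paths": {}}
    matrices, behavior, truth = simulate_mouse_study(mouse_config)
    for tissue, m in matrices.items():
        mp = out / f"matrix_{tissue}.tsv"
        sp = out / f"samples_{tissue}.csv"
        write_expression_tsv(m, mp, sp)
        paths["matrix_paths"][tissue] = str(mp)
        paths["sample_sheet_paths"][tissue] = str(sp)
    behavior.to_csv(out / "behavior.csv", index=False)
    paths["behavior_path"] = str(out / "behavior.csv")
    write_truth(truth, out / "mouse_truth.json")
    paths["mouse_truth"] = str(out / "mouse_truth.json")

    ct_table, clinical, htruth = simulate_human_cohort(human_config)
    ct_table.to_csv(out / "ct.csv", index=False)
    clinical.to_csv(out / "clinical.csv", index=False)
    write_truth(htruth, out / "human_truth.json")
    paths["ct_path"] = str(out / "ct.csv")
    paths["clinical_path"] = str(out / "clinical.csv")
    paths["human_truth"] = str(out / "human_truth.json")
    return paths
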