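"""Candidate aggregation across tissues and generic over-representation.

Combines per-tissue reversal-filter hits, the SAM list, RRHO overlap lists
and a prior human candidate list into one ranked evidence table, plus a
hypergeometric over-representation test with Bonferroni correction as a
generic stand-in for web-based ontology tools.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .rrho import hypergeom_tail

EVIDENCE_FLAGS = (
    "blood_reversal", "dg_reversal", "acc_reversal", "blood_sam",
    "rrho_concordant", "rrho_discordant_dg", "rrho_discordant_acc",
    "stress_specific",
)


def harmonize_symbol(symbol: str, alias_map: dict[str, str] | None = None) -> str:
    """Case-insensitive mouse-to-human symbol translation.

    Default is uppercase identity (Tbc1d10c -> TBC1D10C); an explicit alias
    map (already-uppercased keys) overrides it.
    """
    upper = str(symbol).upper()
    if alias_map:
        return alias_map.get(upper, upper)
    return upper


def venn_counts(lists: dict[str, set[str]]) -> dict[str, int]:
    """Counts for every non-empty region of the Venn diagram of the input
    lists (keyed by '&'-joined sorted member names, exclusive regions)."""
    names = sorted(lists)
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(lists[c] for c in combo))
            outside = set.union(set(), *(lists[c] for c in names if c not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def cross_tissue_candidates(
    reversal_lists: dict[str, pd.DataFrame],
    sam_genes: list[str] | None = None,
    rrho_concordant: list[str] | None = None,
    rrho_discordant: dict[str, list[str]] | None = None,
    stress_specific: list[str] | None = None,
    prior_human: list[str] | None = None,
    alias_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Union evidence table over all candidate sources, plus Venn counts.

    ``reversal_lists`` maps tissue ('blood', 'DG', 'ACC') to the reversal
    filter output; other arguments are plain gene lists.  Candidates are
    ranked by number of evidence flags (descending), then by blood stress p
    (ascending).  Symbols are harmonized case-insensitively before matching
    the prior human list.
    """
    flags: dict[str, set[str]] = {f: set() for f in EVIDENCE_FLAGS}
    stress_sign: dict[str, int] = {}
    blood_p: dict[str, float] = {}

    tissue_flag = {"blood": "blood_reversal", "DG": "dg_reversal", "ACC": "acc_reversal"}
    for tissue, table in reversal_lists.items():
        flag = tissue_flag.get(tissue)
        if flag is None:
            raise DataError(f"unknown tissue {tissue!r}")
        kept = table.index[table["kept"]]
        flags[flag].update(kept)
        for g in kept:
            stress_sign.setdefault(g, int(table.loc[g, "stress_sign"]))
        if tissue == "blood":
            blood_p = table["stress_p"].to_dict()

    flags["blood_sam"].update(sam_genes or [])
    flags["rrho_concordant"].update(rrho_concordant or [])
    for tissue, genes in (rrho_discordant or {}).items():
        key = f"rrho_discordant_{tissue.lower()}"
        if key not in flags:
            raise DataError(f"unknown discordant tissue {tissue!r}")
        flags[key].update(genes)
    flags["stress_specific"].update(stress_specific or [])

    prior = {harmonize_symbol(g, alias_map) for g in (prior_human or [])}
    if prior_human is not None and not prior:
        warnings.warn("prior human list is empty; prior_human_hit all false", stacklevel=2)
    if prior_human is None:
        warnings.warn("no prior human list supplied; prior_human_hit all false", stacklevel=2)

    universe = sorted(set().union(*flags.values()))
    rows = []
    for gene in universe:
        row = {"gene": gene}
        for f in EVIDENCE_FLAGS:
            row[f] = gene in flags[f]
        row["n_flags"] = sum(row[f] for f in EVIDENCE_FLAGS)
        row["prior_human_hit"] = harmonize_symbol(gene, alias_map) in prior
        row["stress_sign"] = stress_sign.get(gene, 0)
        row["blood_stress_p"] = blood_p.get(gene, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["n_flags", "blood_stress_p", "gene"], ascending=[False, True, True]
        ).set_index("gene")
    else:
        table = table.reindex(columns=["gene", *EVIDENCE_FLAGS, "n_flags",
                                       "prior_human_hit", "stress_sign",
                                       "blood_stress_p"]).set_index("gene")

    tissue_sets = {t: set(tbl.index[tbl["kept"]]) for t, tbl in reversal_lists.items()}
    counts = venn_counts(tissue_sets) if tissue_sets else {}
    return table, counts


def ora_enrichment(
    gene_list: list[str],
    gene_sets: dict[str, set[str]],
    background: list[str] | set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation with Bonferroni correction.

    Each set's raw p is the exact upper tail of drawing ``len(gene_list)``
    genes from the background and seeing the observed overlap; corrected p is
    raw p times the number of sets, capped at 1; sets with corrected p below
    ``alpha`` are flagged.
    """
    background = set(background)
    genes = set(gene_list)
    stray = sorted(genes - background)
    if stray:
        raise DataError(f"list genes absent from background: {stray[:10]}")
    if not gene_sets:
        raise DataError("gene set collection is empty")
    m = len(gene_sets)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        if not members:
            raise DataError(f"gene set {name!r} has no members in the background")
        k = len(genes & members)
        p = 1.0 if k == 0 else hypergeom_tail(len(background), len(members), len(genes), k)
        corrected = min(1.0, p * m)
        rows.append({
            "set": name, "set_size": len(members), "overlap": k,
            "p": p, "p_bonferroni": corrected,
            "enriched": bool(k > 0 and corrected < alpha),
        })
    return pd.DataFrame(rows).set_index("set").sort_values("p_bonferroni")
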