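"""End-to-end orchestration: simulate/ingest -> classify -> covariates ->
assemble -> statistics -> report tables.

The report bundle mirrors the result structure of an essentiality study:
zero-order rank correlations among the four covariates, partial rank
correlations of dN/dS with each constraint proxy controlling for the other
two, Kruskal-Wallis tests across the three categories for six variables,
category-composition tests for X-linkage and immunity, and per-category
median summaries with percentile-bootstrap CIs and Holm-adjusted pairwise
Mann-Whitney tests.  All outputs are plain TSV plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assemble as _assemble
from . import goslim as _goslim
from . import network as _network
from . import phenotype as _phenotype
from . import simulate as _simulate
from . import stats as _stats
from . import tau as _tau
from .assemble import ANALYSIS_CATEGORIES

log = logging.getLogger("essevo")

PAIR_VARIABLES = ("dnds", "degree", "multifunctionality", "tau")
GROUP_VARIABLES = ("dnds", "dn", "ds", "degree", "tau", "multifunctionality")


@dataclass
class RunConfig:
    """Paths to the five inputs, or a simulate block, plus analysis knobs."""

    inputs: dict = field(default_factory=dict)  # expression/annotations/...
    simulate: dict | None = None
    tissue_mode: str = "exclude_female_specific"
    male_repro_extra_roots: tuple = ()
    holm_family_dnds: int | None = None  # default: 3 zero-order + 3 partial
    holm_family_posthoc: int = 3
    bootstrap_replicates: int = 100_000
    bootstrap_level: float = 0.95
    seed: int = 0
    mwu_mode: str = "auto"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if not cfg.simulate and not cfg.inputs:
            raise ValueError("config needs either input paths or a simulate block")
        return cfg


@dataclass
class ReportBundle:
    table1: pd.DataFrame  # zero-order correlations
    table2: pd.DataFrame  # partial correlations
    table3: pd.DataFrame  # Kruskal-Wallis
    table4: pd.DataFrame  # composition tests (X-linkage, immunity)
    group_summaries: pd.DataFrame  # per-category medians, CIs, pairwise MWU
    records: pd.DataFrame
    ledger: pd.DataFrame
    manifest: dict

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "table4",
                     "group_summaries", "records", "ledger"):
            df = getattr(self, name)
            df.to_csv(out / f"{name}.tsv", sep="\t",
                      index=name == "records", float_format="%.10g")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


def _result_row(res: _stats.StatResult, **extra) -> dict:
    row = {
        "name": res.name,
        "statistic": res.statistic,
        "df": res.df,
        "p_raw": res.p_raw,
        "p_adjusted": res.p_adjusted,
        "family": res.family,
        "n": str(res.n),
    }
    row.update(extra)
    return row


def correlation_tables(records: pd.DataFrame,
                       family_dnds: int | None = None) -> tuple:
    """Zero-order and partial Spearman tables with Holm adjustment.

    Correlations involving dN/dS (three zero-order plus three partial) form
    one Holm family; the remaining three zero-order correlations form their
    own family of three.
    """
    zero = []
    pairs = []
    for i, a in enumerate(PAIR_VARIABLES):
        for b in PAIR_VARIABLES[i + 1:]:
            res = _stats.spearman(records[a], records[b], name=f"{a}~{b}")
            zero.append(res)
            pairs.append((a, b))

    partial = []
    others = [v for v in PAIR_VARIABLES if v != "dnds"]
    for b in others:
        controls = [records[c].to_numpy() for c in others if c != b]
        res = _stats.partial_spearman(
            records["dnds"], records[b], controls,
            name=f"dnds~{b}|{','.join(c for c in others if c != b)}",
        )
        partial.append(res)

    dnds_family = [r for r, (a, b) in zip(zero, pairs) if "dnds" in (a, b)]
    dnds_family += partial
    m1 = family_dnds if family_dnds is not None else len(dnds_family)
    adj = _stats.holm_adjust([r.p_raw for r in dnds_family], m=m1)
    for r, p in zip(dnds_family, adj):
        r.p_adjusted, r.family = p, f"dnds_correlations(m={m1})"

    other_family = [r for r, (a, b) in zip(zero, pairs) if "dnds" not in (a, b)]
    adj = _stats.holm_adjust([r.p_raw for r in other_family])
    for r, p in zip(other_family, adj):
        r.p_adjusted, r.family = p, f"other_correlations(m={len(other_family)})"

    table1 = pd.DataFrame([_result_row(r) for r in zero])
    table2 = pd.DataFrame([_result_row(r) for r in partial])
    return table1, table2


def kruskal_table(records: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = {c: records[records["category"] == c] for c in ANALYSIS_CATEGORIES}
    for var in GROUP_VARIABLES:
        res = _stats.kruskal_wallis(
            [groups[c][var].to_numpy() for c in ANALYSIS_CATEGORIES],
            name=f"kw_{var}",
        )
        rows.append(_result_row(res, variable=var))
    return pd.DataFrame(rows)


def summarize_groups(records: pd.DataFrame, variable: str,
                     B: int = 100_000, level: float = 0.95, seed: int = 0,
                     m: int = 3, mwu_mode: str = "auto") -> pd.DataFrame:
    """Per-category median + bootstrap CI + Holm-adjusted pairwise MWU."""
    cats = [c for c in ANALYSIS_CATEGORIES
            if (records["category"] == c).any()]
    if len(cats) < 2:
        raise ValueError("need at least two nonempty categories")
    rows = []
    for i, cat in enumerate(cats):
        x = records.loc[records["category"] == cat, variable].to_numpy()
        lo, hi = _stats.bootstrap_median_ci(x, B=B, level=level,
                                            seed=seed + i)
        rows.append({"variable": variable, "kind": "median", "category": cat,
                     "median": float(np.median(x)), "ci_lo": lo, "ci_hi": hi,
                     "n": len(x)})

    tests = []
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            xa = records.loc[records["category"] == a, variable].to_numpy()
            xb = records.loc[records["category"] == b, variable].to_numpy()
            tests.append((a, b, _stats.mann_whitney_u(
                xa, xb, mode=mwu_mode, name=f"mwu_{variable}_{a}_vs_{b}")))
    m_eff = max(m, len(tests))
    adj = _stats.holm_adjust([t.p_raw for _, _, t in tests], m=m_eff)
    for (a, b, t), p in zip(tests, adj):
        rows.append({"variable": variable, "kind": "mwu",
                     "category": f"{a} vs {b}", "statistic": t.statistic,
                     "p_raw": t.p_raw, "p_adjusted": p, "n": str(t.n)})
    return pd.DataFrame(rows)


def composition_table(records: pd.DataFrame, m_posthoc: int = 3,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Category-composition tests for binary flags (immunity, X-linkage).

    The overall test is chi-squared unless any expected count drops below
    five, in which case the exact (Freeman-Halton) test is used; pairwise
    post-hoc tests follow the same rule and are run only when the overall
    test is significant, with Holm adjustment.
    """
    rows = []
    for flag in ("immunity", "x_linked"):
        if flag not in records.columns:
            continue
        counts = []
        for cat in ANALYSIS_CATEGORIES:
            sub = records[records["category"] == cat]
            counts.append((int(sub[flag].sum()), int((~sub[flag]).sum())))
        table = np.array(counts).T  # 2 x 3: flagged / not flagged
        res = _stats.composition_test(table, name=f"composition_{flag}")
        test_name = _stats.choose_test(table)
        for cat, (k, nk) in zip(ANALYSIS_CATEGORIES, counts):
            rows.append({"flag": flag, "scope": cat, "test": "",
                         "proportion_pct": round(100.0 * k / (k + nk), 1),
                         "count": f"{k}/{k + nk}"})
        rows.append({"flag": flag, "scope": "overall", "test": test_name,
                     "statistic": res.statistic, "p_raw": res.p_raw})

        if res.p_raw < alpha:
            pair_tests = []
            for i, a in enumerate(ANALYSIS_CATEGORIES):
                for b in ANALYSIS_CATEGORIES[i + 1:]:
                    ia, ib = (ANALYSIS_CATEGORIES.index(a),
                              ANALYSIS_CATEGORIES.index(b))
                    sub = np.array([counts[ia], counts[ib]]).T
                    pair_tests.append(
                        (a, b, _stats.choose_test(sub),
                         _stats.composition_test(sub)))
            adj = _stats.holm_adjust(
                [t.p_raw for _, _, _, t in pair_tests],
                m=max(m_posthoc, len(pair_tests)))
            for (a, b, tname, t), p in zip(pair_tests, adj):
                rows.append({"flag": flag, "scope": f"{a} vs {b}",
                             "test": tname, "statistic": t.statistic,
                             "p_raw": t.p_raw, "p_adjusted": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def compute_layers(inputs: dict, cfg: RunConfig):
    """Run every covariate stage from input files; returns layer tables."""
    ledger = _assemble.ExclusionLedger()

    rates = _assemble.load_ortholog_rates(inputs["rates"], ledger=ledger)

    edges = _network.read_edge_list(inputs["edges"])
    mapping = _network.read_mapping_table(inputs["mapping"])
    norm_edges, node_genes, _ = _network.normalize_identifiers(edges, mapping)
    net = _network.build_network(norm_edges, node_genes)

    fpkm = _tau.read_fpkm(inputs["expression"])
    tau_series, tau_dropped = _tau.tau_table(fpkm, mode=cfg.tissue_mode)

    go = _goslim.GOGraph.from_obo(inputs["go_obo"])
    annotations = _goslim.read_gaf(inputs["annotations"])
    multifun, go_missing = _goslim.multifunctionality_table(annotations, go)

    ont = _phenotype.MPOntology.from_obo(inputs["mp_obo"])
    allele_rows = _phenotype.read_allele_table(inputs["phenotypes"])
    classifier_cfg = _phenotype.ClassifierConfig(
        male_repro_extra_roots=tuple(cfg.male_repro_extra_roots))
    categories, class_ledger = _phenotype.categorize_dataset(
        allele_rows, ont, classifier_cfg)

    universe = sorted(
        set(rates.index) | set(tau_series.index) | set(multifun.index)
        | set(categories.index)
    )
    degrees, net_missing = _network.degree_table(net, universe)
    log.info("classifier exclusion ledger: %s", class_ledger)
    return {
        "rates": rates, "degrees": degrees, "tau": tau_series,
        "multifun": multifun, "categories": categories,
        "universe": universe, "ingest_ledger": ledger,
    }


def run(cfg: RunConfig, out_dir=None) -> ReportBundle:
    """Execute the full pipeline; deterministic given the config seed."""
    manifest = {"seed": cfg.seed, "tissue_mode": cfg.tissue_mode,
                "bootstrap_replicates": cfg.bootstrap_replicates}
    if cfg.simulate is not None:
        sim_params = dict(cfg.simulate)
        sim_dir = sim_params.pop("out_dir", None)
        sim_cfg = _simulate.SimulationConfig(
            seed=cfg.seed, **sim_params)
        gt = _simulate.simulate_gene_table(sim_cfg)
        if sim_dir is None:
            import tempfile

            tmp = tempfile.TemporaryDirectory(prefix="essevo_sim_")
            sim_dir = tmp.name
            manifest["simulated_inputs"] = "temporary"
        else:
            manifest["simulated_inputs"] = str(sim_dir)
        sim_manifest = _simulate.emit_fixture_files(gt, sim_dir)
        manifest["simulation"] = sim_manifest
        base = Path(sim_dir)
        inputs = {
            "expression": base / "expression_fpkm.tsv",
            "annotations": base / "annotations.gaf",
            "go_obo": base / "go_toy.obo",
            "mp_obo": base / "mp_toy.obo",
            "edges": base / "ppi_edges.tsv",
            "mapping": base / "ppi_mapping.tsv",
            "phenotypes": base / "phenotype_alleles.tsv",
            "rates": base / "ortholog_rates.tsv",
        }
    else:
        inputs = {k: Path(v) for k, v in cfg.inputs.items()}
    manifest["inputs"] = {k: str(v) for k, v in inputs.items()}

    layers = compute_layers(inputs, cfg)
    records, ledger = _assemble.assemble(
        layers["rates"], layers["degrees"], layers["tau"],
        layers["multifun"], layers["categories"],
        gene_universe=layers["universe"],
    )
    records = records[records["category"].isin(ANALYSIS_CATEGORIES)]

    table1, table2 = correlation_tables(records, cfg.holm_family_dnds)
    table3 = kruskal_table(records)
    table4 = composition_table(records, m_posthoc=cfg.holm_family_posthoc)
    summaries = pd.concat(
        [
            summarize_groups(records, var, B=cfg.bootstrap_replicates,
                             level=cfg.bootstrap_level,
                             seed=cfg.seed + 7919 * i,
                             m=cfg.holm_family_posthoc, mwu_mode=cfg.mwu_mode)
            for i, var in enumerate(GROUP_VARIABLES)
        ],
        ignore_index=True,
    )

    full_ledger = pd.concat(
        [layers["ingest_ledger"].to_frame(), ledger.to_frame()],
        ignore_index=True,
    )
    manifest["n_records"] = int(len(records))
    manifest["category_counts"] = (
        records["category"].value_counts().to_dict()
    )
    bundle = ReportBundle(table1, table2, table3, table4, summaries,
                          records, full_ledger, manifest)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
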