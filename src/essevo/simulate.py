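"""Synthetic study generator: gene table, fixtures, and toy ontologies.

Draws a Gaussian-copula gene table whose global Spearman correlation
structure among (dN/dS, node degree, multifunctionality, tau) matches a
target matrix, with per-category location shifts on the latent scale so
the category medians order as observed in knockout studies of testis
proteins (sub-/infertility genes fastest-evolving and most tissue-specific,
lethality genes most connected, multifunctional, and broadly expressed).
Because the category shifts themselves add between-group covariance, the
within-category latent correlation is compensated so that the *mixture*
reproduces the target matrix.

From the ground truth the generator emits the five input files of the
analysis pipeline — expression matrix, GAF annotations, PPI edge list with
identifier mapping, phenotype-allele table, and ortholog substitution
rates — plus small synthetic OBO ontologies (a toy Mammalian Phenotype tree
and a toy GO/GO-slim pair), constructed so every downstream stage recovers
the ground-truth values exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _dist

from .phenotype import (
    CATEGORY_LETHALITY,
    CATEGORY_NONESSENTIAL,
    CATEGORY_SUBINFERTILITY,
)

VARIABLES = ("dnds", "degree", "multifunctionality", "tau")
CATEGORIES = (CATEGORY_SUBINFERTILITY, CATEGORY_LETHALITY, CATEGORY_NONESSENTIAL)

#: analysis tissues (24) followed by the three female-specific tissues
TISSUES_24 = (
    "adrenal_gland", "appendix", "bone_marrow", "brain", "colon",
    "duodenum", "esophagus", "gallbladder", "heart", "kidney", "liver",
    "lung", "lymph_node", "pancreas", "prostate", "rectum",
    "salivary_gland", "skeletal_muscle", "skin", "small_intestine",
    "spleen", "stomach", "testis", "thyroid",
)
TISSUES_FEMALE = ("ovary", "placenta", "uterus")

DEFAULT_TARGET_SPEARMAN = np.array(
    [
        [1.000, -0.229, -0.134, 0.088],
        [-0.229, 1.000, 0.398, -0.304],
        [-0.134, 0.398, 1.000, -0.082],
        [0.088, -0.304, -0.082, 1.000],
    ]
)

#: latent-scale location shifts per (sub-/infertility, lethality, nonessential)
DEFAULT_SHIFTS = {
    "dnds": (0.45, -0.18, 0.16),
    "degree": (-0.35, 0.28, -0.25),
    "multifunctionality": (-0.25, 0.20, -0.20),
    "tau": (0.70, -0.26, 0.22),
    "ds": (-0.35, -0.10, 0.22),
}

#: per-category proportions of X-linked and immunity-annotated genes
DEFAULT_X_LINKED_PROPS = {
    CATEGORY_SUBINFERTILITY: 5 / 57,
    CATEGORY_LETHALITY: 8 / 502,
    CATEGORY_NONESSENTIAL: 27 / 406,
}
DEFAULT_IMMUNITY_PROPS = {
    CATEGORY_SUBINFERTILITY: 11 / 57,
    CATEGORY_LETHALITY: 140 / 502,
    CATEGORY_NONESSENTIAL: 130 / 406,
}

N_SLIM_GENERIC = 40  # size of the toy GO-slim pool (caps multifunctionality)


@dataclass
class SimulationConfig:
    n_genes: int = 965
    category_sizes: tuple = (57, 502, 406)  # sub-/infertility, lethality, nonessential
    target_spearman: np.ndarray = field(
        default_factory=lambda: DEFAULT_TARGET_SPEARMAN.copy()
    )
    n_tissues: int = 24
    seed: int = 0
    shifts: dict = field(default_factory=lambda: dict(DEFAULT_SHIFTS))
    x_linked_props: dict = field(default_factory=lambda: dict(DEFAULT_X_LINKED_PROPS))
    immunity_props: dict = field(default_factory=lambda: dict(DEFAULT_IMMUNITY_PROPS))
    # marginal families (overridable): name -> frozen scipy distribution
    marginals: dict = field(default_factory=dict)

    def __post_init__(self):
        self.target_spearman = np.asarray(self.target_spearman, dtype=float)
        if sum(self.category_sizes) != self.n_genes:
            raise ValueError("category_sizes must sum to n_genes")
        validate_spearman_matrix(self.target_spearman)

    def marginal(self, name: str):
        if name in self.marginals:
            return self.marginals[name]
        return {
            "dnds": _dist.beta(1.6, 14.0),
            "degree": _dist.lognorm(s=1.0, scale=8.0),
            "multifunctionality": _dist.nbinom(4, 0.4),
            "tau": _dist.beta(2.2, 1.5),
            "ds": _dist.gamma(4.0, scale=0.13),
        }[name]


@dataclass
class GroundTruth:
    table: pd.DataFrame
    config: SimulationConfig
    correlation_projected: bool = False
    notes: dict = field(default_factory=dict)


def validate_spearman_matrix(m: np.ndarray):
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.abs(m) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")


def nearest_correlation(m: np.ndarray, eps: float = 1e-8):
    """Project a symmetric matrix to the nearest positive-definite
    correlation matrix (eigenvalue clipping + diagonal rescaling).

    Returns ``(matrix, projected)``.
    """
    w, v = np.linalg.eigh(m)
    if w.min() > eps:
        return m, False
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out, True


def spearman_to_pearson(rho_s: np.ndarray):
    """Gaussian-copula calibration: r = 2*sin(pi*rho_s/6), projected to the
    nearest positive-definite correlation matrix if needed.

    Returns ``(pearson_matrix, projected)``.
    """
    rho_s = np.asarray(rho_s, dtype=float)
    validate_spearman_matrix(rho_s)
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    np.fill_diagonal(r, 1.0)
    return nearest_correlation(r)


def _within_correlation(cfg: SimulationConfig):
    """Within-category latent correlation compensating the shift covariance.

    With mixture weights p_c and shift vectors s_c (demeaned), the shifts
    add B[a,b] = sum_c p_c s_ac s_bc - (sum p s_a)(sum p s_b) to the latent
    covariance.  Setting the within covariance to
    sigma_a*sigma_b*R_target - B (unit within variance, sigma^2 = 1 + B_aa)
    makes the mixture correlation equal the converted target.
    """
    r_target, projected_t = spearman_to_pearson(cfg.target_spearman)
    p = np.array(cfg.category_sizes, dtype=float) / cfg.n_genes
    names = list(VARIABLES) + ["ds"]
    S = np.array([cfg.shifts.get(v, (0.0, 0.0, 0.0)) for v in names])
    mean_s = S @ p
    B = (S * p) @ S.T - np.outer(mean_s, mean_s)
    sigma = np.sqrt(1.0 + np.diag(B))
    k = len(VARIABLES)
    target_full = np.zeros((k + 1, k + 1))
    target_full[:k, :k] = r_target
    target_full[k, k] = 1.0  # ds: no target cross-correlation
    W = np.outer(sigma, sigma) * target_full - B
    np.fill_diagonal(W, 1.0)
    W, projected_w = nearest_correlation(W)
    return W, sigma, S, (projected_t or projected_w)


def simulate_gene_table(cfg: SimulationConfig | None = None) -> GroundTruth:
    """Draw the ground-truth gene table for a simulated study."""
    cfg = cfg or SimulationConfig()
    rng = np.random.Generator(np.random.Philox(cfg.seed))
    n = cfg.n_genes
    W, sigma, S, projected = _within_correlation(cfg)
    if np.linalg.eigvalsh(W).min() <= 0:  # pragma: no cover
        raise ValueError("latent correlation not positive definite")

    # category labels in random order, sizes exact
    labels = np.repeat(np.arange(3), cfg.category_sizes)
    labels = labels[rng.permutation(n)]

    chol = np.linalg.cholesky(W)
    z = rng.standard_normal((n, len(VARIABLES) + 1)) @ chol.T
    names = list(VARIABLES) + ["ds"]
    for j, v in enumerate(names):
        z[:, j] += np.asarray(cfg.shifts.get(v, (0.0, 0.0, 0.0)))[labels]
    u = _dist.norm.cdf(z / sigma)

    cols = {}
    cols["dnds"] = cfg.marginal("dnds").ppf(u[:, 0])
    degree = np.maximum(1, np.ceil(cfg.marginal("degree").ppf(u[:, 1])))
    cols["degree"] = np.minimum(degree, n - 1).astype(int)
    mf = cfg.marginal("multifunctionality").ppf(u[:, 2]).astype(int) + 1
    cols["multifunctionality"] = np.minimum(mf, N_SLIM_GENERIC)
    cols["tau"] = cfg.marginal("tau").ppf(u[:, 3])
    cols["ds"] = cfg.marginal("ds").ppf(u[:, 4])
    cols["dn"] = cols["dnds"] * cols["ds"]

    table = pd.DataFrame(cols)
    table.insert(0, "category", [CATEGORIES[c] for c in labels])
    table.index = [f"gene{i + 1:05d}" for i in range(n)]
    table.index.name = "gene_id"

    # X-linkage and immunity flags: deterministic per-category counts,
    # random membership
    for col, props in (("x_linked", cfg.x_linked_props),
                       ("immunity", cfg.immunity_props)):
        flag = np.zeros(n, dtype=bool)
        for c, cat in enumerate(CATEGORIES):
            idx = np.flatnonzero(labels == c)
            count = int(round(props.get(cat, 0.0) * len(idx)))
            chosen = rng.choice(idx, size=count, replace=False)
            flag[chosen] = True
        table[col] = flag

    # tissue of maximal expression: testis-biased for sub-/infertility genes
    tissues = np.array(TISSUES_24[: cfg.n_tissues])
    max_tissue = tissues[rng.integers(0, len(tissues), size=n)]
    subfert = labels == 0
    testis_biased = rng.random(n) < 0.8
    if "testis" in tissues:
        max_tissue[subfert & testis_biased] = "testis"
    table["max_tissue"] = max_tissue

    return GroundTruth(table, cfg, correlation_projected=projected)


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, index=True):
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_toy_mp_obo(path: Path):
    """Synthetic miniature Mammalian Phenotype tree (is_a only)."""
    terms = [
        ("MP:0000001", "mammalian phenotype", None),
        ("MP:0010770", "preweaning lethality", "MP:0000001"),
        ("MP:0011100", "preweaning lethality, complete penetrance", "MP:0010770"),
        ("MP:0011110", "preweaning lethality, incomplete penetrance", "MP:0010770"),
        ("MP:0008569", "lethality at weaning", "MP:0000001"),
        ("MP:0008571", "lethality at weaning, complete penetrance", "MP:0008569"),
        ("MP:0011400", "complete lethality", "MP:0000001"),
        ("MP:0010831", "partial lethality", "MP:0000001"),
        ("MP:0008770", "decreased survivor rate", "MP:0000001"),
        ("MP:0010769", "abnormal survival", "MP:0000001"),
        ("MP:0001924", "infertility", "MP:0000001"),
        ("MP:0001925", "male infertility", "MP:0001924"),
        ("MP:0001926", "female infertility", "MP:0001924"),
        ("MP:0001922", "reduced male fertility", "MP:0000001"),
        ("MP:0001935", "decreased litter size", "MP:0000001"),
        ("MP:0002210", "abnormal sex determination", "MP:0000001"),
        ("MP:0001145", "abnormal male reproductive system morphology", "MP:0000001"),
        ("MP:0001146", "abnormal testis morphology", "MP:0001145"),
        ("MP:0005560", "decreased circulating glucose level", "MP:0000001"),
    ]
    lines = ["format-version: 1.2", "ontology: mp-toy (synthetic fixture)", ""]
    for tid, name, parent in terms:
        lines += [f"[Term]", f"id: {tid}", f"name: {name}"]
        if parent:
            lines.append(f"is_a: {parent}")
        lines.append("")
    path.write_text("\n".join(lines))


def slim_generic_ids():
    return [f"GO:70000{i:02d}" for i in range(1, N_SLIM_GENERIC + 1)]


def _slim_child(slim_id: str) -> str:
    return slim_id.replace("GO:70000", "GO:71000")


IMMUNITY_SLIM = "GO:0002376"
IMMUNITY_CHILD = "GO:7100000"


def write_toy_go_obo(path: Path):
    """Synthetic miniature GO BP tree with a goslim_generic subset."""
    lines = ["format-version: 1.2", "ontology: go-toy (synthetic fixture)",
             "subsetdef: goslim_generic \"Generic GO slim\"", ""]

    def term(tid, name, parent=None, slim=False, part_of=None):
        lines.extend(["[Term]", f"id: {tid}", f"name: {name}",
                      "namespace: biological_process"])
        if slim:
            lines.append("subset: goslim_generic")
        if parent:
            lines.append(f"is_a: {parent}")
        if part_of:
            lines.append(f"relationship: part_of {part_of}")
        lines.append("")

    term("GO:0008150", "biological_process", slim=True)
    term(IMMUNITY_SLIM, "immune system process", parent="GO:0008150", slim=True)
    term(IMMUNITY_CHILD, "toy immune subprocess", parent=IMMUNITY_SLIM)
    for sid in slim_generic_ids():
        term(sid, f"toy slim process {sid}", parent="GO:0008150", slim=True)
        term(_slim_child(sid), f"toy specific process under {sid}",
             part_of=sid)
    path.write_text("\n".join(lines))


def _emit_expression(gt: GroundTruth, path: Path):
    """Invert tau for one-dominant-tissue profiles (peak FPKM 100)."""
    table = gt.table
    tissues = list(TISSUES_24[: gt.config.n_tissues]) + list(TISSUES_FEMALE)
    peak = 100.0
    data = np.empty((len(table), len(tissues)))
    for i, (gene, row) in enumerate(table.iterrows()):
        baseline = peak * (1.0 - row["tau"])
        data[i, :] = baseline
        j = tissues.index(row["max_tissue"])
        data[i, j] = peak
    df = pd.DataFrame(data, index=table.index, columns=tissues)
    df.index.name = "gene_id"
    _write_tsv(df, path)


def _emit_gaf(gt: GroundTruth, path: Path, rng):
    slims = slim_generic_ids()
    lines = ["!gaf-version: 2.1"]
    for gene, row in gt.table.iterrows():
        m = int(row["multifunctionality"])
        chosen = []
        if row["immunity"]:
            chosen.append(IMMUNITY_CHILD)
            m -= 1
        picks = rng.choice(len(slims), size=m, replace=False)
        chosen.extend(_slim_child(slims[i]) for i in sorted(picks))
        for go_id in chosen:
            cols = ["SYN", gene, gene.upper(), "", go_id, "SYN:0000001",
                    "IDA", "", "P", "", "", "protein", "taxon:9606",
                    "20150101", "SYN", "", ""]
            lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def _repair_degree_sequence(degrees: np.ndarray):
    """Adjust a degree sequence by +-1 steps until it is graphical."""
    seq = degrees.astype(int).copy()
    repairs = []
    n = len(seq)
    seq = np.minimum(seq, n - 1)
    if seq.sum() % 2 == 1:
        i = int(np.argmin(seq))
        seq[i] += 1
        repairs.append((i, +1))
    while not nx.is_graphical(seq.tolist()):
        i = int(np.argmax(seq))
        seq[i] -= 1
        repairs.append((i, -1))
        if seq.sum() % 2 == 1:
            j = int(np.argmin(seq))
            seq[j] += 1
            repairs.append((j, +1))
    return seq, repairs


def _emit_network(gt: GroundTruth, edge_path: Path, map_path: Path):
    """Havel-Hakimi realization of the ground-truth degree sequence.

    Infeasible sequences are repaired by +-1 adjustments; the ground-truth
    table is updated to the realized degrees so the round trip is exact.
    """
    table = gt.table
    seq, repairs = _repair_degree_sequence(table["degree"].to_numpy())
    graph = nx.havel_hakimi_graph(seq.tolist())
    realized = np.array([graph.degree(i) for i in range(len(seq))])
    # pair genes and graph nodes with equal degree
    order_gene = np.argsort(-seq, kind="mergesort")
    order_node = np.argsort(-realized, kind="mergesort")
    accession_of = {}
    gene_ids = list(table.index)
    for gi, ni in zip(order_gene, order_node):
        accession_of[ni] = (f"SP{gi + 1:05d}", gene_ids[gi], int(realized[ni]))

    rows = []
    for a, b in sorted(graph.edges()):
        rows.append((accession_of[a][0], accession_of[b][0]))
    pd.DataFrame(rows, columns=["accession_a", "accession_b"]).to_csv(
        edge_path, sep="\t", index=False
    )

    realized_by_gene = {}
    mapping_rows = []
    for ni, (acc, gene, deg) in sorted(accession_of.items()):
        realized_by_gene[gene] = deg
        mapping_rows.append(
            {"accession": acc, "status": "current", "replacement": "",
             "gene_ids": gene, "biotype": "protein_coding",
             "reviewed": "true", "hgnc_protein_coding": "false"}
        )
    mapping_rows.sort(key=lambda r: r["accession"])
    pd.DataFrame(mapping_rows).to_csv(map_path, sep="\t", index=False)
    gt.table["degree"] = [realized_by_gene[g] for g in table.index]
    return repairs


_LETHAL_VARIANTS = ("MP:0011100", "MP:0010770", "MP:0008571", "MP:0011400")
_SUBFERT_VARIANTS = ("MP:0001925", "MP:0001922")


def _emit_phenotypes(gt: GroundTruth, path: Path):
    rows = []
    for i, (gene, row) in enumerate(gt.table.iterrows()):
        zygosity = "hemizygous" if row["x_linked"] else "homozygous"
        if row["category"] == CATEGORY_LETHALITY:
            term = _LETHAL_VARIANTS[i % len(_LETHAL_VARIANTS)]
            flags = "confirmed_prepubertal_death" if term == "MP:0011400" else ""
        elif row["category"] == CATEGORY_SUBINFERTILITY:
            term = _SUBFERT_VARIANTS[i % len(_SUBFERT_VARIANTS)]
            flags = ""
        else:
            term = "MP:0005560"
            flags = ""
        rows.append(
            {"gene_id": gene, "allele_id": f"{gene}_a1",
             "allele_type": "Targeted",
             "allele_attributes": "Null/knockout",
             "n_targeted_genes": 1, "zygosity": zygosity, "sex": "both",
             "mp_terms": term, "curation_flags": flags,
             "x_linked": str(row["x_linked"]).lower()}
        )
        if i % 11 == 0:  # decoy allele that the filter must drop
            rows.append(
                {"gene_id": gene, "allele_id": f"{gene}_a2",
                 "allele_type": "Spontaneous",
                 "allele_attributes": "Null/knockout",
                 "n_targeted_genes": 1, "zygosity": "homozygous",
                 "sex": "both", "mp_terms": "MP:0010770",
                 "curation_flags": "", "x_linked": str(row["x_linked"]).lower()}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _emit_rates(gt: GroundTruth, path: Path, rng):
    table = gt.table
    autosomes = rng.integers(1, 23, size=len(table)).astype(str)
    df = pd.DataFrame(
        {
            "gene_id": table.index,
            "homology_type": "1-to-1",
            "dn": table["dn"].to_numpy(),
            "ds": table["ds"].to_numpy(),
            "dnds": table["dnds"].to_numpy(),
            "masked": "false",
            "chromosome": np.where(table["x_linked"], "X", autosomes),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def emit_fixture_files(gt: GroundTruth, out_dir) -> dict:
    """Write all five pipeline inputs plus toy ontologies and a manifest.

    Uses a generator seeded from the simulation seed, so the same config
    yields byte-identical files.  Returns the manifest (paths, repairs,
    projection flag); also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.Philox(gt.config.seed + 2**20))

    paths = {
        "expression": out / "expression_fpkm.tsv",
        "annotations": out / "annotations.gaf",
        "go_obo": out / "go_toy.obo",
        "mp_obo": out / "mp_toy.obo",
        "edges": out / "ppi_edges.tsv",
        "mapping": out / "ppi_mapping.tsv",
        "phenotypes": out / "phenotype_alleles.tsv",
        "rates": out / "ortholog_rates.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_toy_mp_obo(paths["mp_obo"])
    write_toy_go_obo(paths["go_obo"])
    repairs = _emit_network(gt, paths["edges"], paths["mapping"])
    _emit_expression(gt, paths["expression"])
    _emit_gaf(gt, paths["annotations"], rng)
    _emit_phenotypes(gt, paths["phenotypes"])
    _emit_rates(gt, paths["rates"], rng)
    _write_tsv(gt.table, paths["ground_truth"])

    manifest = {
        "seed": gt.config.seed,
        "n_genes": gt.config.n_genes,
        "category_sizes": list(gt.config.category_sizes),
        "correlation_projected": bool(gt.correlation_projected),
        "degree_repairs": len(repairs),
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
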