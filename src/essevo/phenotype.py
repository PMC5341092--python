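"""Essentiality classification from mouse knockout-allele phenotypes.

Each gene is assigned one of three categories from the Mammalian Phenotype
(MP) annotations of its targeted null alleles:

* ``lethality`` — death before puberty at sub-Mendelian ratios (preweaning
  lethality MP:0010770 or lethality at weaning MP:0008569, with subterms;
  or one of four broader survival terms when the literature-curation flag
  confirms prepubertal death),
* ``male_subinfertility`` — male in-/subfertility (MP:0001925, MP:0001922)
  or another male-reproductive phenotype confirmed by curation,
* ``nonessential`` — phenotypic null alleles with neither kind of evidence.

Genes with evidence for both kinds of essentiality, unclear or fertile
status, litter-size-only phenotypes, phenotypes requiring extra
manipulation, or flagged special cases are excluded with a recorded reason.
Manual literature checks cannot be recomputed and enter as curation flags
on the input rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

LETHALITY_SUBTREE_ROOTS = ("MP:0010770", "MP:0008569")
LETHALITY_SINGLE_TERMS = frozenset(
    {"MP:0011400", "MP:0010831", "MP:0008770", "MP:0010769"}
)
MALE_INFERTILITY_TERMS = ("MP:0001925", "MP:0001922")
DECREASED_LITTER_SIZE = "MP:0001935"

CATEGORY_LETHALITY = "lethality"
CATEGORY_SUBINFERTILITY = "male_subinfertility"
CATEGORY_NONESSENTIAL = "nonessential"
CATEGORY_EXCLUDED = "excluded"
CATEGORY_NO_DATA = "no_data"

#: exclusion reasons in precedence order (highest first)
EXCLUSION_PRECEDENCE = (
    "double_essentiality",
    "unclear_or_fertile",
    "decreased_litter_size_only",
    "requires_extra_manipulation",
    "special_case_exclude",
)


@dataclass
class PhenotypeAlleleRow:
    gene_id: str
    allele_id: str
    allele_type: str
    allele_attributes: frozenset
    n_targeted_genes: int
    zygosity: str  # homozygous | hemizygous | other
    sex: str = "both"
    mp_terms: frozenset = frozenset()
    curation_flags: frozenset = frozenset()
    x_linked: bool = False

    def __post_init__(self):
        self.allele_attributes = frozenset(self.allele_attributes)
        self.mp_terms = frozenset(self.mp_terms)
        self.curation_flags = frozenset(self.curation_flags)
        if self.n_targeted_genes < 1:
            raise ValueError("n_targeted_genes must be >= 1")


@dataclass
class CategoryAssignment:
    gene_id: str
    category: str
    evidence: list = field(default_factory=list)
    exclusion_reason: str | None = None


@dataclass
class ClassifierConfig:
    """MP term sets driving classification; all IDs literal "MP:" strings.

    ``male_repro_extra_roots`` holds additional male-reproductive phenotype
    roots (expanded with subterms) that count as sub-/infertility evidence
    only together with the curation flag ``confirmed_male_subinfertility``;
    the default is empty — only the two printed in-/subfertility terms are
    hard evidence — and the list is user-extensible.
    """

    lethality_subtree_roots: tuple = LETHALITY_SUBTREE_ROOTS
    lethality_single_terms: frozenset = LETHALITY_SINGLE_TERMS
    male_infertility_terms: tuple = MALE_INFERTILITY_TERMS
    male_repro_extra_roots: tuple = ()
    decreased_litter_size_term: str = DECREASED_LITTER_SIZE


class MPOntology:
    """Mammalian Phenotype ontology restricted to is_a edges."""

    def __init__(self, graph: nx.MultiDiGraph):
        self.graph = graph

    @classmethod
    def from_obo(cls, path) -> "MPOntology":
        return cls(obonet.read_obo(path))

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def subtree(self, root: str) -> set:
        """Root plus all transitive is_a descendants."""
        if root not in self.graph:
            raise KeyError(f"unknown MP term {root}")
        seen = {root}
        stack = [root]
        while stack:
            cur = stack.pop()
            for child, _, rel in self.graph.in_edges(cur, keys=True):
                if rel == "is_a" and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen


def mp_subtree(ont: MPOntology, root: str) -> set:
    return ont.subtree(root)


def filter_alleles(rows, require_x_linked_for_hemizygous: bool = True):
    """Keep targeted single-gene null alleles with usable zygosity.

    A row survives when allele_type is "Targeted", its attributes contain
    "Null/knockout", it targets exactly one gene, and its zygosity is
    homozygous or — for X-linked genes — hemizygous.
    """
    kept = []
    for row in rows:
        if row.allele_type != "Targeted":
            continue
        if "Null/knockout" not in row.allele_attributes:
            continue
        if row.n_targeted_genes != 1:
            continue
        if row.zygosity == "homozygous":
            pass
        elif row.zygosity == "hemizygous":
            if require_x_linked_for_hemizygous and not row.x_linked:
                continue
        else:
            continue
        kept.append(row)
    return kept


def _evidence_sets(ont: MPOntology, cfg: ClassifierConfig):
    lethal = set()
    for root in cfg.lethality_subtree_roots:
        lethal |= ont.subtree(root)
    extra_repro = set()
    for root in cfg.male_repro_extra_roots:
        if root in ont:
            extra_repro |= ont.subtree(root)
        else:
            warnings.warn(f"male-reproductive root {root} not in ontology")
            extra_repro.add(root)
    return lethal, extra_repro


def classify_gene(gene_id: str, rows, ont: MPOntology,
                  cfg: ClassifierConfig | None = None) -> CategoryAssignment:
    """Assign one essentiality category from a gene's filtered alleles."""
    cfg = cfg or ClassifierConfig()
    if not rows:
        return CategoryAssignment(gene_id, CATEGORY_NO_DATA,
                                  exclusion_reason="no_phenotype_data")
    if any(r.gene_id != gene_id for r in rows):
        raise ValueError("rows must all belong to gene_id")

    lethal_terms, extra_repro = _evidence_sets(ont, cfg)
    infertility = set(cfg.male_infertility_terms)
    repro_all = infertility | extra_repro | {cfg.decreased_litter_size_term}

    lethal_evidence = []
    subfert_evidence = []
    repro_seen = False
    flags = set()
    for row in rows:
        flags |= row.curation_flags
        female_specific = "female_specific_phenotype" in row.curation_flags
        for term in sorted(row.mp_terms):
            if term in lethal_terms:
                lethal_evidence.append((row.allele_id, f"lethality_subtree:{term}"))
            elif (term in cfg.lethality_single_terms
                  and "confirmed_prepubertal_death" in row.curation_flags):
                lethal_evidence.append((row.allele_id, f"lethality_single:{term}"))
            if not female_specific:
                if term in infertility:
                    subfert_evidence.append((row.allele_id, f"male_infertility:{term}"))
                elif (term in extra_repro
                      and "confirmed_male_subinfertility" in row.curation_flags):
                    subfert_evidence.append((row.allele_id, f"male_repro_confirmed:{term}"))
                if term in repro_all:
                    repro_seen = True

    return apply_exclusions(
        gene_id,
        lethal_evidence=lethal_evidence,
        subfert_evidence=subfert_evidence,
        repro_seen=repro_seen,
        flags=flags,
    )


def apply_exclusions(gene_id: str, lethal_evidence, subfert_evidence,
                     repro_seen: bool, flags: set) -> CategoryAssignment:
    """Resolve evidence and curation flags into a final assignment.

    Exclusions fire in fixed precedence order; the female-specific flag
    never creates sub-/infertility evidence (handled upstream) but does not
    itself exclude a gene.
    """
    male_repro_association = bool(subfert_evidence) or repro_seen
    if lethal_evidence and male_repro_association:
        return CategoryAssignment(
            gene_id, CATEGORY_EXCLUDED,
            evidence=lethal_evidence + subfert_evidence,
            exclusion_reason="double_essentiality",
        )
    if ("fertile_despite_abnormality" in flags or "fertility_increasing" in flags):
        return CategoryAssignment(gene_id, CATEGORY_EXCLUDED,
                                  exclusion_reason="unclear_or_fertile")
    if "decreased_litter_size_only_homozygous_pairs" in flags:
        return CategoryAssignment(gene_id, CATEGORY_EXCLUDED,
                                  exclusion_reason="decreased_litter_size_only")
    if "requires_extra_manipulation" in flags:
        return CategoryAssignment(gene_id, CATEGORY_EXCLUDED,
                                  exclusion_reason="requires_extra_manipulation")
    if "special_case_exclude" in flags:
        return CategoryAssignment(gene_id, CATEGORY_EXCLUDED,
                                  exclusion_reason="special_case_exclude")
    if subfert_evidence:
        return CategoryAssignment(gene_id, CATEGORY_SUBINFERTILITY,
                                  evidence=subfert_evidence)
    if lethal_evidence:
        return CategoryAssignment(gene_id, CATEGORY_LETHALITY,
                                  evidence=lethal_evidence)
    return CategoryAssignment(gene_id, CATEGORY_NONESSENTIAL)


def categorize_dataset(rows, ont: MPOntology,
                       cfg: ClassifierConfig | None = None):
    """Classify every gene in an allele table.

    Returns ``(assignments DataFrame, ledger)`` where the ledger counts
    genes per exclusion reason (plus genes whose alleles were all filtered
    out, under ``no_phenotype_data``).
    """
    cfg = cfg or ClassifierConfig()
    by_gene: dict = {}
    for row in rows:
        by_gene.setdefault(row.gene_id, []).append(row)

    assignments = []
    ledger: dict = {}
    for gene_id in sorted(by_gene):
        surviving = filter_alleles(by_gene[gene_id])
        assignment = classify_gene(gene_id, surviving, ont, cfg)
        assignments.append(assignment)
        if assignment.exclusion_reason:
            ledger[assignment.exclusion_reason] = (
                ledger.get(assignment.exclusion_reason, 0) + 1
            )

    df = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "category": [a.category for a in assignments],
            "exclusion_reason": [a.exclusion_reason for a in assignments],
            "n_evidence": [len(a.evidence) for a in assignments],
        }
    ).set_index("gene_id")
    return df, ledger


def read_allele_table(path) -> list:
    """Read a phenotype-allele TSV into :class:`PhenotypeAlleleRow` objects.

    Set-valued columns (attributes, MP terms, flags) are pipe-separated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            PhenotypeAlleleRow(
                gene_id=rec.gene_id,
                allele_id=rec.allele_id,
                allele_type=rec.allele_type,
                allele_attributes=frozenset(
                    v for v in rec.allele_attributes.split("|") if v
                ),
                n_targeted_genes=int(rec.n_targeted_genes),
                zygosity=rec.zygosity,
                sex=rec.sex,
                mp_terms=frozenset(v for v in rec.mp_terms.split("|") if v),
                curation_flags=frozenset(
                    v for v in rec.curation_flags.split("|") if v
                ),
                x_linked=rec.x_linked.lower() in ("true", "1", "yes"),
            )
        )
    return rows
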