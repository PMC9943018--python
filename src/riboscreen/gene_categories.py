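"""Ten-way functional categorization of antisense-regulated genes.

The original screen curated each regulated gene by hand against pathway and
orthology databases; here that step is replaced by an ordered, user-editable
rule file. Each rule matches on gene kind, annotation labels (keywords, COG
ids, EC prefixes), gene length, ortholog presence, and optionally the
riboswitch family; the first matching rule wins and the final fallback is
``other``, so the classifier is total.

Categories: five biologically consistent groups (interconversion, cofactor,
transporter, signaling, tf), three suspect structural groups (transposase,
pseudogene) and annotation artifacts (hypothetical: under 300 nt with no
ortholog; uncharacterized: at least 300 nt with a bona fide ortholog), and
the fallback (other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .genome_io import GeneFeature
from .orientation import OrientationCall

log = logging.getLogger(__name__)

CATEGORIES = ("interconversion", "cofactor", "transporter", "signaling", "tf",
              "transposase", "pseudogene", "uncharacterized", "hypothetical",
              "other")

#: the groups whose regulation is biologically consistent with the ligand
CONSISTENT_CATEGORIES = ("interconversion", "cofactor", "transporter",
                         "signaling", "tf")


@dataclass(frozen=True, slots=True)
class CategoryRule:
    category: str
    keywords: tuple[str, ...] = ()
    cogs: tuple[str, ...] = ()
    kind: str | None = None
    min_length: int | None = None
    max_length: int | None = None
    requires_ortholog: bool | None = None
    families: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def matches(self, gene: GeneFeature, family: str, has_ortholog: bool) -> bool:
        if self.kind is not None and gene.kind != self.kind:
            return False
        if self.min_length is not None and gene.length_nt < self.min_length:
            return False
        if self.max_length is not None and gene.length_nt > self.max_length:
            return False
        if self.requires_ortholog is not None \
                and has_ortholog != self.requires_ortholog:
            return False
        if self.families and family not in self.families:
            return False
        if self.keywords or self.cogs:
            blob = " ".join(sorted(gene.labels)).lower()
            if not (any(k.lower() in blob for k in self.keywords)
                    or any(c.lower() in blob for c in self.cogs)):
                return False
        return True


@dataclass(frozen=True)
class CategoryRuleSet:
    rules: tuple[CategoryRule, ...]
    min_real_gene_nt: int = 300

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule set is empty")
        last = self.rules[-1]
        unconditional = (not last.keywords and not last.cogs and not last.families
                         and last.kind is None and last.min_length is None
                         and last.max_length is None
                         and last.requires_ortholog is None)
        if last.category != "other" or not unconditional:
            raise ValueError("rule set must end with an unconditional "
                             "'other' fallback")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "CategoryRuleSet":
        doc = yaml.safe_load(Path(source).read_text())
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "CategoryRuleSet":
        rules = tuple(CategoryRule(
            category=spec["category"],
            keywords=tuple(spec.get("keywords", ())),
            cogs=tuple(spec.get("cogs", ())),
            kind=spec.get("kind"),
            min_length=spec.get("min_length"),
            max_length=spec.get("max_length"),
            requires_ortholog=spec.get("requires_ortholog"),
            families=tuple(spec.get("families", ())),
        ) for spec in doc["rules"])
        return cls(rules=rules, min_real_gene_nt=doc.get("min_real_gene_nt", 300))

    @classmethod
    def default(cls) -> "CategoryRuleSet":
        ref = resources.files("riboscreen.data").joinpath("category_rules.yaml")
        return cls._from_doc(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True, slots=True)
class CategoryAssignment:
    gene_id: str
    category: str
    matched_rule: str
    genome_id: str = ""


def classify_gene(gene: GeneFeature, family: str, has_ortholog: bool,
                  rules: CategoryRuleSet) -> CategoryAssignment:
    """First matching rule wins; total by construction."""
    for i, rule in enumerate(rules.rules):
        if rule.matches(gene, family, has_ortholog):
            return CategoryAssignment(gene_id=gene.gene_id, category=rule.category,
                                      matched_rule=f"{i}:{rule.category}",
                                      genome_id=gene.genome_id)
    raise AssertionError("unreachable: rule set ends with a fallback")


def categorize_all(calls: Iterable[OrientationCall],
                   genes: Iterable[GeneFeature] | Mapping[tuple[str, str], GeneFeature],
                   ortholog_presence: set | Mapping,
                   rules: CategoryRuleSet | None = None) -> list[CategoryAssignment]:
    """One assignment per distinct antisense-targeted gene.

    ``ortholog_presence`` is a set (or mapping) of (genome_id, gene_id) keys
    with known orthologs. A gene targeted by several riboswitches (tandem
    arrangements) is assigned once, under the family of the first call in
    locus order. Calls whose gene is missing from the annotation are
    assigned ``other`` with a warning.
    """
    rules = rules or CategoryRuleSet.default()
    if not isinstance(genes, Mapping):
        genes = {(g.genome_id, g.gene_id): g for g in genes}
    seen: set[tuple[str, str]] = set()
    out: list[CategoryAssignment] = []
    for call in sorted(calls, key=lambda c: c.locus_id):
        if call.relation != "ANTISENSE_3P":
            continue
        key = (call.genome_id, call.target_gene_id)
        if key in seen:
            continue
        seen.add(key)
        gene = genes.get(key)
        if gene is None:
            log.warning("antisense target %s/%s missing from annotation; "
                        "assigned 'other'", *key)
            out.append(CategoryAssignment(gene_id=call.target_gene_id,
                                          category="other",
                                          matched_rule="missing-gene-record",
                                          genome_id=call.genome_id))
            continue
        out.append(classify_gene(gene, call.family, key in ortholog_presence,
                                 rules))
    return out
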