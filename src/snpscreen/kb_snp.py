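"""Knowledge-based SNP selection (KB-SNP).

Keeps a SNP when at least one of its annotated genes carries a GO term
from a target list (e.g. transporter activity and related functions).
The target list is used verbatim by default; closure over the ontology
graph (is_a / part_of descendants) is an explicit opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from snpscreen.core_data import SnpAnnotation

logger = logging.getLogger("snpscreen")


@dataclass
class KbSelection:
    """Selected SNP ids plus, per SNP, the (gene, matched GO terms) evidence."""

    selected_snp_ids: list[str]
    justification: dict[str, list[tuple[str, list[str]]]]

    def __post_init__(self) -> None:
        for sid in self.selected_snp_ids:
            if not self.justification.get(sid):
                raise ValueError(f"selected SNP {sid} has no justification")

    def __len__(self) -> int:
        return len(self.selected_snp_ids)


def expand_term_set(ontology, seeds: list[str],
                    relations: set[str] = frozenset({"is_a", "part_of"})) -> list[str]:
    """Seeds plus all descendants reachable through the chosen relations.

    ``ontology`` is an OBO graph as loaded by :func:`obonet.read_obo`
    (a networkx MultiDiGraph whose edges point child -> parent).  The
    result is deterministic: seeds first in input order, then new
    descendants in sorted order.
    """
    bad_rel = set(relations) - {"is_a", "part_of"}
    if bad_rel:
        raise ValueError(f"unsupported relations: {sorted(bad_rel)}")
    unknown = [s for s in seeds if s not in ontology]
    if unknown:
        raise ValueError(f"seed accession(s) not in ontology: {unknown}")
    found: set[str] = set(seeds)
    # obonet edges run child -> parent with the relation as the edge key,
    # so descendants are in-neighbours through matching keys
    stack = list(seeds)
    while stack:
        term = stack.pop()
        for child, _, key in ontology.in_edges(term, keys=True):
            if key in relations and child not in found:
                found.add(child)
                stack.append(child)
    extra = sorted(found - set(seeds))
    return list(seeds) + extra


def select_snps_by_go(
    annotation: Mapping[str, SnpAnnotation],
    gene_go: Mapping[str, set[str]],
    targets: list[str],
) -> KbSelection:
    """Select SNPs whose genes carry at least one target GO term.

    SNPs with no gene annotation (e.g. intergenic) are never selected.
    Selection order follows the annotation mapping; justification records
    every (gene, matching accessions) pair.
    """
    target_set = set(targets)
    selected: list[str] = []
    justification: dict[str, list[tuple[str, list[str]]]] = {}
    for snp_id, ann in annotation.items():
        evidence: list[tuple[str, list[str]]] = []
        for gene in sorted(ann.gene_symbols):
            hits = sorted(gene_go.get(gene, set()) & target_set)
            if hits:
                evidence.append((gene, hits))
        if evidence:
            selected.append(snp_id)
            justification[snp_id] = evidence
    if not selected:
        logger.info("KB-SNP selection is empty (%d SNPs screened, %d target terms)",
                    len(annotation), len(target_set))
    return KbSelection(selected, justification)


def write_selection_tsv(selection: KbSelection, path: str | Path) -> None:
    rows = [
        {"snp_id": sid, "gene": gene, "matched_terms": ",".join(terms)}
        for sid in selection.selected_snp_ids
        for gene, terms in selection.justification[sid]
    ]
    pd.DataFrame(rows, columns=["snp_id", "gene", "matched_terms"]).to_csv(
        path, sep="\t", index=False
    )
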