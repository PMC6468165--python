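"""Editing-site coordinate system and gene template compilation.

Kinetoplastid U-indel editing inserts and deletes uridines between the
encoded (non-T, in cDNA sense) bases of an mRNA.  An *editing site* (ES) is
any gap between two consecutive non-T nucleotides; the number of Ts in that
gap is the site's U count.  Editing proceeds 3'->5', so sites are numbered
1 = 3'-most.  A gene is described by a pre-edited and a fully edited
template that share the same non-T *skeleton* and differ only in per-site
U counts, flanked by never-edited 5'/3' regions used as alignment anchors.

The site scan runs from the last (non-T) base of the 5' flank to the first
(non-T) base of the 3' flank, so the gaps abutting the flanks are in-domain
sites: a domain whose strictly internal skeleton has K bases exposes m = K+1
editing sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_DNA = set("ACGT")
_RNA_TO_DNA = str.maketrans("acgtuU", "ACGTTT")


class TemplateError(ValueError):
    """A gene template violates the editing-site model."""


def as_dna(seq: str) -> str:
    """Uppercase a sequence and map U->T (internal alphabet is DNA)."""
    return seq.translate(_RNA_TO_DNA)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class GeneTemplate:
    """User-supplied description of one edited gene.

    ``pre_edited`` and ``fully_edited`` are complete amplicon references
    (cDNA sense, 5'->3') that both begin with ``flank5`` and end with
    ``flank3`` verbatim.  ``es_offset`` maps local site 1 (the 3'-most gap)
    to the published editing-site label, e.g. es_offset=441 labels local
    sites 1, 2, ... as ES441, ES442, ...
    """

    gene_name: str
    pre_edited: str
    fully_edited: str
    flank5: str
    flank3: str
    es_offset: int = 1

    def __post_init__(self):
        for name in ("pre_edited", "fully_edited", "flank5", "flank3"):
            object.__setattr__(self, name, as_dna(getattr(self, name)))


def _gap_scan(scan: str) -> tuple[str, list[int]]:
    """Split a scan string into (skeleton, U counts per gap, 5'->3')."""
    skeleton = scan.replace("T", "")
    runs = [len(g) for g in re.split("[ACG]", scan)]
    # runs[0]/runs[-1] are outside the terminal skeleton bases of the scan
    return skeleton, runs[1:-1]


@dataclass(frozen=True)
class EditingSiteTable:
    """Per-site U counts of both templates in 3'->5' site coordinates.

    ``skeleton`` is the strictly internal non-T skeleton of the editing
    domain (5'->3').  ``pre_U``/``full_U`` are vectors of length
    ``n_sites = len(skeleton) + 1`` indexed so that element 0 is site 1,
    the 3'-most gap.
    """

    gene_name: str
    skeleton: str
    pre_U: np.ndarray
    full_U: np.ndarray
    flank5: str
    flank3: str
    es_offset: int = 1

    def __post_init__(self):
        object.__setattr__(self, "pre_U", np.asarray(self.pre_U, dtype=int))
        object.__setattr__(self, "full_U", np.asarray(self.full_U, dtype=int))
        if len(self.pre_U) != len(self.full_U) or len(self.pre_U) != len(self.skeleton) + 1:
            raise TemplateError("pre_U/full_U length must equal len(skeleton)+1")
        if (self.pre_U < 0).any() or (self.full_U < 0).any():
            raise TemplateError("U counts must be non-negative")
        self.pre_U.setflags(write=False)
        self.full_U.setflags(write=False)

    @property
    def n_sites(self) -> int:
        return len(self.skeleton) + 1

    @property
    def requires_editing(self) -> np.ndarray:
        return self.pre_U != self.full_U

    def site_label(self, local: int) -> int:
        """Published label of a local site index (1 = 3'-most).

        Local index 0 (``no canonical progress``) maps to the label of the
        site immediately 3' of the domain, i.e. ``es_offset - 1``.
        """
        return self.es_offset + local - 1

    def local_site(self, label: int) -> int:
        local = label - self.es_offset + 1
        if not 1 <= local <= self.n_sites:
            raise KeyError(f"site label ES{label} outside domain of {self.gene_name}")
        return local

    def render_domain(self, u_counts) -> str:
        """Rebuild the editing-domain string (between the flanks) from U counts."""
        u = np.asarray(u_counts, dtype=int)
        if len(u) != self.n_sites:
            raise ValueError("u_counts length mismatch")
        if (u < 0).any():
            raise ValueError("u_counts must be non-negative")
        parts = ["T" * int(u[self.n_sites - 1])]
        for j, base in enumerate(self.skeleton):
            parts.append(base)
            parts.append("T" * int(u[self.n_sites - 2 - j]))
        return "".join(parts)

    def render_read(self, u_counts) -> str:
        return self.flank5 + self.render_domain(u_counts) + self.flank3

    @property
    def pre_domain(self) -> str:
        return self.render_domain(self.pre_U)

    @property
    def full_domain(self) -> str:
        return self.render_domain(self.full_U)


def _domain_of(seq: str, flank5: str, flank3: str, what: str) -> str:
    if not seq.startswith(flank5):
        raise TemplateError(f"{what} template does not begin with flank5")
    if not seq.endswith(flank3):
        raise TemplateError(f"{what} template does not end with flank3")
    return seq[len(flank5):len(seq) - len(flank3)]


def validate_template(config: GeneTemplate) -> list[str]:
    """Return every violated template invariant (empty list iff valid)."""
    issues: list[str] = []
    for name in ("pre_edited", "fully_edited", "flank5", "flank3"):
        bad = set(getattr(config, name)) - _DNA
        if bad:
            issues.append(f"{name} contains non-ACGT characters: {sorted(bad)}")
    if issues:
        return issues
    if not config.flank5 or config.flank5.endswith("T"):
        issues.append("flank5 must be non-empty and end on a non-T base")
    if not config.flank3 or config.flank3.startswith("T"):
        issues.append("flank3 must be non-empty and begin on a non-T base")
    domains = {}
    for what, seq in (("pre-edited", config.pre_edited), ("fully edited", config.fully_edited)):
        try:
            domains[what] = _domain_of(seq, config.flank5, config.flank3, what)
        except TemplateError as exc:
            issues.append(str(exc))
    if len(domains) == 2:
        sk_pre = domains["pre-edited"].replace("T", "")
        sk_full = domains["fully edited"].replace("T", "")
        if sk_pre != sk_full:
            pos = next(
                (i for i, (a, b) in enumerate(zip(sk_pre, sk_full)) if a != b),
                min(len(sk_pre), len(sk_full)),
            )
            issues.append(
                "pre-edited and fully edited domains have diverging non-T "
                f"skeletons (first divergence at skeleton position {pos}: "
                f"{sk_pre[pos:pos + 1] or '-'} vs {sk_full[pos:pos + 1] or '-'})"
            )
    return issues


def build_site_table(config: GeneTemplate) -> EditingSiteTable:
    """Compile a gene template into its editing-site table.

    Raises :class:`TemplateError` naming the first violated invariant; use
    :func:`validate_template` to collect all of them.
    """
    issues = validate_template(config)
    if issues:
        raise TemplateError(issues[0])
    pre_dom = _domain_of(config.pre_edited, config.flank5, config.flank3, "pre-edited")
    full_dom = _domain_of(config.fully_edited, config.flank5, config.flank3, "fully edited")
    scan_pre = config.flank5[-1] + pre_dom + config.flank3[0]
    scan_full = config.flank5[-1] + full_dom + config.flank3[0]
    skeleton, pre_gaps = _gap_scan(scan_pre)
    _, full_gaps = _gap_scan(scan_full)
    # gaps are 5'->3'; site vectors are 3'->5'
    table = EditingSiteTable(
        gene_name=config.gene_name,
        skeleton=skeleton[1:-1],
        pre_U=np.array(pre_gaps[::-1], dtype=int),
        full_U=np.array(full_gaps[::-1], dtype=int),
        flank5=config.flank5,
        flank3=config.flank3,
        es_offset=config.es_offset,
    )
    # round-trip guarantee
    assert table.render_domain(table.pre_U) == pre_dom
    assert table.render_domain(table.full_U) == full_dom
    return table


def table_from_counts(
    gene_name: str,
    skeleton: str,
    pre_U,
    full_U,
    flank5: str,
    flank3: str,
    es_offset: int = 1,
) -> EditingSiteTable:
    """Build a site table directly from skeleton + U counts (synthetic genes)."""
    table = EditingSiteTable(gene_name, as_dna(skeleton), pre_U, full_U,
                             as_dna(flank5), as_dna(flank3), es_offset)
    cfg = GeneTemplate(
        gene_name,
        table.render_read(table.pre_U),
        table.render_read(table.full_U),
        flank5,
        flank3,
        es_offset,
    )
    issues = validate_template(cfg)
    if issues:
        raise TemplateError(issues[0])
    return table
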