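"""Compile a gene template into an editing-site table.

An editing site (ES) is any gap between two non-T bases of the cDNA;
sites are numbered 3'->5', the direction editing proceeds.  The table
records how many Us each template carries at each site.
"""

from uindel import GeneTemplate, build_site_table

cfg = GeneTemplate(
    gene_name="toy",
    pre_edited="GACGA",        # flank5 + unedited domain + flank3
    fully_edited="GATCGTTA",   # same skeleton, Us inserted at two sites
    flank5="G",
    flank3="A",
    es_offset=441,             # local site 1 carries the published label ES441
)
table = build_site_table(cfg)

print(f"{table.n_sites} editing sites, skeleton {table.skeleton!r}")
for local in range(1, table.n_sites + 1):
    i = local - 1
    flag = "edited" if table.requires_editing[i] else "unchanged"
    print(f"  ES{table.site_label(local)}: pre={table.pre_U[i]} full={table.full_U[i]} ({flag})")
# Sites where pre and full U counts differ are the sites editing must
# change; the 3'-most site is listed first because editing starts there.
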