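# uindel

Analysis of editing progression in kinetoplastid U-insertion/deletion RNA
editing from targeted amplicon sequencing.

Mitochondrial mRNAs of trypanosomes are matured by inserting and deleting
uridines (Us) under the direction of guide RNAs (gRNAs). Deep sequencing of
an edited region yields a mixture of pre-edited, partially edited and fully
edited molecules; the partially edited ones record where editing pauses and
what the machinery mis-writes. `uindel` implements that analysis for anyone
studying editing progression: align amplicon reads to the pre-edited and
fully edited templates in *editing-site coordinates*, classify and landmark
every transcript, find pause sites, characterize junctions, and test which
gRNAs could have templated an observed sequence. A synthetic read generator
with exact ground truth stands in for deposited sequencing data.

## The model

An **editing site (ES)** is any gap between two non-T bases of the cDNA,
numbered 1 = 3′-most because editing proceeds 3′→5′. A transcript's U
counts per site define its landmarks:

- **ESS** (editing stop site): the 5′-most site up to which the transcript
  matches the fully edited template, all 3′ sites matching too;
- **JSS/JES**: the junction start (ESS + 1) and end (5′-most site with any
  editing action); **JL** = JES − ESS, the junction length.

Reads whose non-T skeleton deviates from the template (sequencing errors)
are excluded; the rest are normalized to 100 000 per sample. Pausing is
quantified on the stop-site histogram *H* over sites 0..m:

- **Intrinsic pause site (IPS)**: H(s) > Q3 + 1.5·IQR (Tukey outlier rule),
  required in ≥ 4 of 5 replicates;
- **Exacerbated pause site (EPS)**: H(s) increases under knockdown of an
  editing factor with Student's-t *P* < 0.05 and Benjamini–Hochberg
  *q* < 0.05, consistently in every induced replicate (pre-edited reads
  dropped and the rest renormalized first).

Guide RNAs are modelled as antiparallel duplexes with Watson–Crick and G:U
wobble pairs: a guide anchors through its 5′ region 3′ of the block it
edits, and walking 3′→5′ each skeleton base must pair the next guide base
while intervening guide purine runs template that many Us. Bulging a single
mRNA-pairing U shifts the register and merges runs — the misalignment
mechanism that turns a canonical 5-U block into 9 Us.

## Worked example

```python
from uindel import detect_ips
from uindel.simulate import SimulationParams, demo_gene, generate_population

table = demo_gene()                     # packaged synthetic 30-site gene
params = SimulationParams(table=table, depth=100_000, n_replicates=5,
                          spikes=((3, 20.0), (17, 20.0)))
pops = [s.to_population() for s in generate_population(params, seed=1)]
for row in detect_ips(pops, min_support=4).itertuples():
    print(f"ES{row.site_label}: support {row.support}/{row.n_replicates}, "
          f"{row.fold_over_threshold:.1f}-fold above threshold")
```

prints

```
ES438: support 5/5, 17.3-fold above threshold
ES452: support 5/5, 17.2-fold above threshold
```

— the two stop sites whose pausing was raised 20-fold above background are
called in all five replicates, and no background site is; the fold value
says how far each pause exceeds the per-replicate outlier threshold. The
`examples/` directory walks through every capability the same way
(site tables, classification, IPS, EPS, junctions, gRNA search), and the
`uindel` command exposes each stage as a subcommand (`uindel simulate`,
`align`, `quantify`, `ips`, `eps`, `junctions`, `grna-search`) for
shell-driven runs on FASTA/FASTQ input.

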