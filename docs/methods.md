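# Methods

## Coordinate model

Templates are handled as cDNA (DNA alphabet; U on input maps to T). A gene
is configured by its pre-edited and fully edited sequences plus two
never-edited flanks; both templates must begin/end with the flanks
verbatim and share the same non-T skeleton. Editing sites are the gaps
between consecutive non-T bases scanned from the last base of the 5′ flank
to the first base of the 3′ flank — flanks are therefore constrained to
end/begin on a non-T base, so the boundary gaps are well defined and edge
insertions (junctions abutting the anchor region) are representable. A
domain whose strictly internal skeleton has K bases exposes m = K + 1
sites. Sites are indexed 1 = 3′-most internally; published labels are a
pure offset (`es_offset`), which is a configuration value because flank
coordinates are primer choices, not properties of the gene.

## Alignment and landmarks

Reads are anchored by exact match of both flanks, trying the forward
sequence first and then the reverse complement (merged-pair orientation is
instrument-dependent). The outermost placements — first flank5 occurrence,
last flank3 occurrence after it — delimit the domain, which is
deterministic for every read, including degenerate short flanks. Anything
without both flanks is *unanchored*; an extracted domain whose non-T
skeleton deviates from the template is a *non-standard alignment*. Both
are tallied in QC and excluded from analysis: flanks are primer-defined
and never edited, and a non-T mismatch anywhere means the read cannot be
expressed as U counts on the template skeleton. FASTQ qualities are read
and discarded; the pipeline operates on sequence identity only.

Classification is exact-match against the two templates (pre-edited
checked first, so a gene needing no editing at some sites still classes an
unedited read as pre-edited). ESS is the longest matching prefix against
the fully edited counts, with 0 meaning no canonical progress; the label
reported for ESS 0 is the site 3′ of the domain (`es_offset - 1`). A pause
"followed by pre-edited sequence" with no canonical progress is simply a
pre-edited read and never enters stop-site statistics.

## Normalization and pausing

Standard alignments are rescaled so each sample totals 100 000; normalized
counts stay fractional throughout (no rounding rule is imposed on
downstream statistics). The stop-site histogram covers every site 0..m
zero-filled — the class exclusions (pre-edited, fully edited) decide which
*reads* are counted, not which sites exist, and the outlier statistic
needs the full distribution.

The IPS threshold is Q3 + 1.5·(Q3 − Q1) with quartiles by linear
interpolation of order statistics (the default convention of mainstream
statistics environments; the convention matters for sites near the
threshold, which is why per-replicate thresholds are included in the
output). Consensus calls report the support count so full-support sites
remain distinguishable from n−1-support sites, and the fold over threshold
is the mean across replicates of H(s) divided by that replicate's own
threshold (a pooled-threshold variant would conflate replicate depths).

EPS testing uses the equal-variance Student's t-test by default (Welch
behind a flag). Zero-variance sites get p = 1 when the group means agree
and a machine-epsilon variance floor otherwise — decisive without
manufacturing a statistic from 0/0. BH correction runs across all sites of
one transcript in one comparison. "Significantly increased in both
replicates" with n = 2 induced samples is operationalized as the group
test plus per-replicate direction consistency (every induced replicate
above the uninduced mean); an alternative that tests each induced
replicate separately against the uninduced group is available as
`rule="per_replicate"`. By default pre-edited reads are dropped and the
remainder renormalized before testing, so the comparison concerns
transcripts that entered the editing pathway; fully edited reads are
retained in that pool (a flag drops them too, since either choice is
defensible). Calls whose mean renormalized count is below 500 in both
groups carry a low-abundance annotation rather than being suppressed.

## Junctions

Junction families are grouped by exact U-count identity; pattern-based
grouping (exact count / canonical / pre-edited / any, per site) is
available through `SitePredicate` for signatures such as hybrid junctions
(a non-canonical run flanked by canonical editing on both sides). A
sequence absent from a replicate contributes zero to the cross-replicate
average — "average normalized count" over n replicates is only well
defined with zero fill. The share denominator is selectable (all sequences
at that stop site, all that entered the pathway, or the whole sample)
because different questions need different baselines. Junction lengths are
binned 0 / 1–2 / 11–13 by default; bins must not overlap.

## Guide templating

Duplexes are antiparallel and ungapped, scored +2 per Watson–Crick pair,
+1 per G:U wobble, −2 per mismatch (configurable); ties break toward the
3′-most mRNA placement. Anchors extend 5′ along the mRNA from a position
pairing the guide's 5′ terminus while a mismatch budget holds, never end
on a mismatch, and rank by (mismatches, length, 3′ position).

The templating walk consumes the guide 5′→3′ from the anchor while moving
3′→5′ along the skeleton. A guide G is ambiguous (pairs C by WC or U by
wobble); it is consumed greedily by the next skeleton base when it can
pair it, otherwise it joins the purine run templating insertions — greedy
register-following is deterministic and reproduces canonical blocks for
guides that are exact antiparallel complements. A zero-length purine run
templates zero Us, which is how U deletions are expressed (the templated
count is simply below the pre-edited count). When a skeleton base cannot
pair any remaining guide base the register is broken; Us templated 3′ of
the break are still reported, because insertion precedes the failed
pairing in editing order — this is exactly what the single-U bulge mode
produces: removing one mRNA-pairing U from the walk merges the flanking
purine runs (5 + 4 → 9 Us) and then stalls. Guide search uses fixed-length
anchors (`min_anchor`, default 6, ≤ 1 mismatch, wobble allowed — the
tolerances are configurable because no canonical values exist) so the
templating register starts immediately 5′ of the anchor; candidates rank
by exactly-explained sites, then duplex score, and guides annotated to
other transcripts are searched identically because guide utilization can
be promiscuous.

## Synthetic data

The generator emulates a targeted amplicon study of a minimally edited
mitochondrial transcript. Per replicate, in fixed draw order (class
counts, stop-site counts, per-site mechanism counts, perturbation details
in ascending site order, T-run jitter, error thinning — the order is part
of the seed contract, and replicate k uses
`default_rng(SeedSequence(seed).spawn(n)[k])`):

- class ~ multinomial(p_pre, p_partial, p_full); defaults 0.25/0.50/0.25,
  in the range such studies report for minimally edited transcripts;
- partial reads stop at ESS ~ categorical over the sites whose 5′
  neighbour requires editing, uniform unless spiked; designated spikes
  model intrinsic or exacerbated pauses;
- junction content by mechanism mixture: none (pre-edited 5′ of the stop;
  only available once some canonical editing occurred, otherwise the read
  would be pre-edited and the draw falls back to perturbation), random
  per-site U jitter over a junction of random length (length weights are
  bimodal, short-dominant with a secondary 11–13 mode, matching how such
  junction-length distributions are binned), cognate-guide misalignment
  (a 9-U run at the site 5′ of the designated stop, half the time followed
  by canonically edited sequence — 'hybrid' junctions), and
  alternative-guide templating (a fixed pattern derived from the packaged
  alternative guide);
- substitution errors hit non-T positions at rate ε (default 0.002,
  MiSeq-scale) and change the base to another non-T base, so every errored
  read is non-standard or unanchored by construction — the exclusion
  filter and junction analytics can be tested independently. An optional
  T-run jitter mode instead perturbs one site's U count, producing
  plausible mis-edits that stay standard.

The packaged demo gene is synthetic: 30 sites, mostly insertions with
three deletion sites and several never-edited sites, and adjacent 5-U/4-U
canonical runs separated by an encoded A so the one-U bulge mechanism is
expressible. Its labels are offset to place the run pair at ES447/ES448.
Ground-truth landmarks are computed on the true U-count vector; at ε = 0
the pipeline must recover them from the emitted sequence exactly, which is
what the round-trip tests assert.

What the generator does not model: PCR amplification bias and chimeras,
quality-score structure, indel sequencing errors, between-replicate
library composition drift, and any correlation between neighbouring stop
sites. Passing tests therefore demonstrate correctness of the analysis
under the stated statistical structure, not robustness to every artifact
of real libraries.

## Problem sizes and numerical choices

Validation scenarios run at the study's scale — 100 000 reads per
replicate, 5 wild-type replicates, 2 induced vs 8 uninduced — with 100
seeds for IPS recovery and 200 null comparisons for EPS type-I control;
the acceptance script uses 50 null comparisons. Tolerances: exact equality
for landmarks and templated counts; `1e-6`-relative for normalization
identities; recovery criteria as stated in the tests (≥95/100 IPS runs,
≤10% null EPS rate, 3 binomial SE for class fractions). Degenerate inputs:
empty samples raise, zero-variance sites are defined as above, an
all-zero histogram yields threshold 0 (a site is an outlier only if
strictly above it).

## Known limitations

Exact flank matching means primer-region sequencing errors discard reads
rather than rescuing them; no fuzzy anchoring is attempted. Junction
mechanisms are assigned independently per read, so mechanism mixtures are
identifiable only in aggregate. The guide search considers ungapped
duplexes plus the explicit single-base bulge; thermodynamic folding is out
of scope.
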