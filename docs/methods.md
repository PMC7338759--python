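# Methods

## Coordinate and overlap conventions

All intervals are 0-based half-open (`[start, end)`), the native convention
of BED, bedGraph and BEDPE.  Published enhancer tables print 1-based
inclusive coordinates; the packaged link-table fixture stores them as
printed and shifts starts by −1 on load.  "Intersection" means >= 1 shared
base everywhere (catalog merging, peak classification, contact anchors);
adjacent half-open intervals do not intersect.  The center of an interval is
`floor((start+end)/2)`, so odd-length intervals resolve deterministically.
Chromosome names are compared by exact string equality — no `chr` aliasing —
and a validation warning lists name sets missing from one input but present
in another.

## Catalog and classification

Two enhancer sets (stable-eRNA/CAGE-derived and nascent-eRNA/GRO-seq-derived)
are pooled and records sharing >= 1 bp are merged into one enhancer spanning
their union.  The merged record's eRNA expression is the **max** of its
constituents: the sources measure different transcript populations on
different scales, and max preserves the strongest evidence of activity while
being independent of merge order.  Constituent names are retained in a
provenance field.  Catalog records are named `enh_0001…` in genomic sort
order.  Classification tests the whole enhancer body against the peak set
(>= 1 bp anywhere, not just the center); an empty peak set is legal and
leaves every enhancer unbound.

## Signal profiling

Windows of ±`flank` (default 1000 bp, binned at 10 bp) are anchored on the
enhancer **center**.  Bin values are means of per-base signal; bases not
covered by the track — including bases beyond either chromosome end — read
0, the bedGraph sparsity convention.  The class comparison reports the grand
mean over all (region, base) pairs per class and their bound/unbound ratio;
with equal-width windows this equals the mean of per-region means, which is
what the significance test uses.  The test is the two-sided Wilcoxon
rank-sum on per-region window means — the same test used for the eRNA
expression comparison — with Benjamini–Hochberg adjustment across tracks.
Exact enumeration is used when both samples have n <= 8 and no ties;
otherwise the normal approximation with tie correction and *without*
continuity correction, so identical samples give p = 1 exactly.  A zero
unbound mean yields a NaN ratio (undefined, never infinite).

## Promoters and target assignment

Promoters are strand-aware windows from 1 kb upstream to 500 bp downstream
of the TSS (1500 bp; reflected on the minus strand; clipped at position 0
with a warning).  Three evidence types are computed independently for every
(bound enhancer, significantly DE target) pair and a link is emitted iff at
least one holds — the union, not a cascade:

* **TAD co-membership** — one TAD contains both the enhancer center and the
  promoter TSS.  Representative points avoid undefined behavior for
  boundary-straddling intervals; `tad_mode="overlap"` switches to full
  >= 1 bp interval overlap with a single TAD.  TADs must be pairwise
  non-overlapping per chromosome (validated).
* **Chromatin contact** — some contact has one anchor overlapping the
  enhancer and the other overlapping the promoter, in either orientation.
* **Distance** — mRNA: promoter within 100 kb of the enhancer, boundary
  inclusive.  miRNA: linkage score S = (B − A)/(A + B) with A and B the
  distances from the enhancer center to the closest miRNA and closest
  non-miRNA gene **TSS** (TSS rather than gene-body edge, because every
  annotation the procedure consumes is TSS-anchored).  B deliberately
  excludes miRNA genes — otherwise B <= A whenever a miRNA is the nearest
  gene of all, and the score would never discriminate.  Association requires
  S strictly below 0.2, algebraically equivalent to B < 1.5·A.  When several
  miRNAs tie at distance A, all tied miRNAs receive the evidence
  (deterministic order by gene id).

As written, S < 0.2 also holds whenever the nearest non-miRNA gene is closer
than the nearest miRNA (S <= 0).  The score is implemented exactly as
defined; `require_mirna_closer=True` optionally adds the condition A <= B
for users who want the rule restricted to miRNA-proximal geometry.

Distances to genes on other chromosomes are undefined (a `None` sentinel),
never "very large"; cross-chromosome pairs can only be linked by contact
evidence.

DE thresholds: q-value strictly below 0.05, |log2FC| >= 1 inclusive,
following the printed symbols of the standard rule.  Only significant
features enter the target universe, but nearest-gene distances for the
miRNA score are measured against the full annotation.

Set statistics: the driver-gene overlap fraction is |A ∩ B| / |B| with the
**reference list B as denominator** (an empty reference returns 0 with a
warning).  Over-representation is the one-sided hypergeometric tail with
fold = observed/expected and BH adjustment across gene sets in batch calls.

## Synthetic genome

The generator emulates the *products* of the upstream assays, not the
assays: intervals, coverage, contacts and DE tables, never reads or
sequence.  Defaults define the tested study conditions: 4 chromosomes of
5 Mb tiled by 20 TADs each (250 kb), 200 enhancers of 600 bp with bound
fraction 0.3, bound/unbound bump amplitude ratio 2.0 (unbound amplitude 10,
Gaussian bump sd 150 bp), truncated-normal noise floor sd 0.5, log-normal
eRNA expression with a ×2 bound-class shift, one expected planted target per
bound enhancer, planted |log2FC| centered on 2, and contact records retained
with probability `contact_recall`.

Geometry is engineered so the planted links are the only recoverable pairs:
each bound enhancer occupies its own TAD near its middle; TADs are wide
enough (validated: 0.42 × width must exceed the mRNA distance window) that
no target is within 100 kb of a foreign bound enhancer; contact-planted
targets sit in TADs with no bound enhancer, spaced >= 5 kb apart so no
promoter strays into another pair's anchor; and every bound enhancer gets
two never-DE "guard" genes — a miRNA at ~5 kb and a non-miRNA at ~9 kb —
pinning its nearest-gene distances so the S rule fires only where planted
(guard geometry keeps B >= 1.5·A, and the nearest miRNA is non-DE anyway).
Distance-planted miRNA targets are placed with B < 1.4·A so the rule fires
with margin.  Background genes are never significant and stay >= 12 kb from
bound enhancer centers.  Only planted targets receive q < 0.05.

Consequences used by the tests: with `noise_sd = 0` the class signal ratio
is *exactly* the planted amplitude ratio (all enhancers share one length and
bump shape, and track values are written at full float precision); link
recovery has precision = recall = 1; lowering `contact_recall` removes
exactly the withheld contact-only links.  With the default noise the
measured ratio sits ~5 % below the planted 2.0 — the truncated-normal noise
floor adds the same positive offset to both class means — comfortably inside
the 10 % recovery band the tests assert.

What the generator does **not** emulate: read-count noise (DE q-values are
fabricated directly, since DE model fitting is upstream of this package),
irregular TAD sizes, background chromatin contacts, overlapping or nested
enhancers beyond the two-source merge, and sequence content of any kind.
Passing recovery tests therefore demonstrate correctness of the interval
logic and integration rules under clean geometry, not robustness to
annotation error or biological confounding.

Determinism: one `numpy` generator seeded from the config drives every
draw, floats are serialized with `repr`, and identical configs produce
byte-identical bundles.

## Pipeline and problem sizes

`run_all` executes catalog → classify → profile → DE filter → link and
writes `catalog.tsv`, `comparisons.tsv`, `profiles.tsv`, `links.tsv` and
`report.json`; outputs carry no timestamps, so reruns on unchanged inputs
are byte-identical.  The `report` stage is folded into `run-all` (the report
is written by the same pass that computes each count, so report fields can
never drift from stage outputs).  Tests and the acceptance script use the
default 200-enhancer genome, 20-seed replicate sets for the stochastic
recovery checks, and exhaustive enumeration only where it is cheap
(rank-sum with n = 3, hypergeometric universes <= 30) — sizes chosen so the
planted effects are detected with wide margins while the whole suite stays
fast.

## Known limitations

* The two-source merge collapses any >= 1 bp overlap; no attempt is made to
  resolve partially overlapping enhancers into distinct units.
* TAD evidence in point mode ignores enhancers whose center falls in an
  inter-TAD gap even when most of the body lies inside a TAD (use
  `tad_mode="overlap"` if that matters).
* The contact test is anchor-overlap only; it does not weight by contact
  frequency or filter by interaction distance.
* The miRNA distance rule evaluates only the closest miRNA per enhancer; a
  second-nearest DE miRNA can never gain distance evidence, matching the
  rule's definition but limiting sensitivity in miRNA-dense loci.
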