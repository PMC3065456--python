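# Methods

## Problem

A drug-metabolizing gene (the phenol-conjugating UDP-glucuronosyltransferase
exon studied across Carnivora) has been lost independently in several
hypercarnivorous lineages. Given (i) codon alignments of the exon across
species, (ii) a dated phylogeny with node ages in millions of years (MYA),
and (iii) diet classifications, the package answers four questions:

1. **Which sequences are pseudogenes?** Detect gene-inactivating lesions —
   frameshifting indels and premature stop codons — per species, and merge
   them into shared mutation events.
2. **When did each lesion become fixed?** Bound the fixation time of each
   event by the crown and stem ages of its carrier clade.
3. **Is selective constraint relaxed in carrier lineages?** Estimate
   lineage-specific dN/dS under a codon substitution model and test it
   against the all-species average (and against neutrality) with
   likelihood-ratio tests.
4. **Does gene loss track diet?** Cross-tabulate gene status against the
   Van Valkenburgh diet categories.

A seeded synthetic codon-evolution generator (`simgen`) supplies test data
for the whole chain, so no external sequence download is needed.

## Coordinates and lesion conventions (`seqio`, `lesionscan`)

All lesion coordinates are 1-based reference positions, +1 being the adenine
of the reference start codon; the reference must start in frame (offset ≡ 1
mod 3). Alignment columns are internal and never reported. Deletions are the
inclusive span of deleted reference bases (a 1 bp deletion is one position);
insertions are the flanking reference pair (p, p+1). Indels are disruptive
iff length mod 3 ≠ 0; nonsense codons always are.

Nonsense codons are called **in the unshifted reference frame**: the species
bases aligned to each reference codon are read off directly (insertion
columns skipped, codons touching gaps or ambiguity codes skipped; a species
codon matching a reference stop — i.e. a terminal stop — is not an event).
Stops that appear only in the shifted frame downstream of a frameshift are
consequences of the causal indel, not independent events; with per-species
gap columns this falls out of reference-frame scanning automatically. The
convention matches how the lesion tables in this literature count events:
one frameshift plus its downstream stops is one mutation.

Events are merged across species by (kind, start, end, length) only —
inserted nucleotides are not compared, and a merge of indels with different
inserted sequence is logged. Event ids are assigned deterministically by
position then kind. A species is called a pseudogene iff it carries at least
one disruptive event.

A nonsense event is flagged as a **CpG hotspot** when its stop codon is one
sense-strand C→T transition (e.g. CGA→TGA) or one G→A change (antisense
C→T) away from a non-stop codon observed at the same position in at least
one non-carrier — the signature of recurrent deamination of methylated CpG
sites, and hence grounds to prefer independent origins over shared descent
when the same stop appears in unrelated lineages.

## Fixation-time bounds (`chronomap`)

For carriers forming a monophyletic clade, the lesion must have become fixed
after the clade split from its sister (stem age = age of the MRCA's parent,
the upper bound) and before the clade's own crown radiation (crown age, the
lower bound; 0 for a single carrier). Display follows the field's shorthand:
`<U MYA` when the lower bound is 0, `>L MYA` when the carriers span the
whole tree (no outgroup information). The Dollo assumption — a lesion arises
once and never reverts — is fixed, not configurable: reversal of a
frameshift or stop is biologically implausible. Non-monophyletic carrier
sets are decomposed into maximal monophyletic clades, one independent origin
each. Tips with no sequence data (e.g. lineages where the gene could not be
amplified) are treated as missing and excluded from carrier and non-carrier
sets alike; they are never evidence of absence. Node ages are point
estimates; published CI annotations can be carried through on the interval
bounds but no resampling or CI arithmetic is performed.

On simulated data the true origin time is uniform on the origin branch, so
the reported interval covers it by construction; the test suite checks this
coverage property over random replicates.

## Codon model and fitting (`codonml`)

The substitution model is the Goldman–Yang codon model: a reversible Markov
chain on the 61 sense codons with rate q_ij = π_j · κ^[transition] ·
ω^[nonsynonymous] for single-nucleotide changes, 0 otherwise, scaled so one
unit of branch length is one expected substitution per codon. ω = dN/dS may
differ by labelled branch class (branch model). Default codon frequencies
are F3×4 (position-specific nucleotide frequencies, floored at 1e-8 and
renormalized); equal, F1×4 and empirical (+0.5 pseudocount) are switchable.
The default masking policy drops any codon column containing a gap, stop, or
ambiguity in any sequence; a per-sequence mode treats such codons as missing
in that sequence only; with masking off, a stop codon in the data is an
error naming the species and site.

Likelihoods use Felsenstein pruning over unique site patterns with per-node
rescaling. Transition matrices come from the symmetric eigendecomposition of
the reversibility-symmetrized generator (D^{1/2} Q D^{-1/2}), which is
stable and makes P(t) cheap to re-evaluate along one branch. A bifurcating
root of a reversible model leaves only the sum of the two root edges
identifiable, so one of them is pinned during fitting when both edges share
a branch class.

Fitting alternates two stages to convergence (absolute log-likelihood change
< 1e-8, at most 25 rounds):

* a bounded quasi-Newton (L-BFGS-B) step on log κ and the log ω of each free
  class (κ ∈ [0.01, 100], ω ∈ [1e-4, 999]);
* one-dimensional line searches on every branch length in [1e-8, 25],
  evaluated analytically in the eigenbasis: with the partial likelihoods
  above and below an edge held fixed, the per-site likelihood along that
  edge is Σ_k C_k·exp(λ_k t), so each Brent evaluation is a dot product.

Starting values are κ = 2, ω = 0.4, branch lengths 0.1 (or the tree's own
lengths when present); optional restarts perturb the global stage
deterministically. The scheme involves no randomness, so fits are exactly
reproducible. Degenerate inputs (no variable codon site) short-circuit with
ω = NaN, minimal branch lengths and a `degenerate` flag. An ω reaching the
cap of 999 (dS ≈ 0 on the class) is reported as 999 with a `capped` flag and
a warning that the estimate is unreliable.

**Tests.** Model 0 fits a single ω (the "average value"). The branch model
frees one ω per class; the lineage-vs-average test pins the foreground ω to
the Model-0 estimate in the null while the background ω stays free (1 df);
the lineage-vs-neutral test pins it to 1.0 instead. LRT statistics are
2ΔlnL against the chi-square upper tail; a negative 2ΔlnL beyond tolerance
(1e-4) is an optimization failure and raises. The foreground of a named
clade is its crown branches plus the stem by default (`include_stem=False`
gives crown-only; which labelling a given published analysis used is often
unstated, so both are supported). Branch lengths are re-estimated per fit by
default; `reuse_from=` shares one fit's branch lengths and κ across nested
fits as common nuisance parameters.

**Calibration design** (`calibration`). The neutral-recovery study simulates
16-taxon, 500-codon alignments with κ = 2, ω = 1 and refits Model 0; the
LRT-size study simulates 12-taxon, 300-codon alignments under a single
ω = 0.4 (the typical purifying-selection average seen in this gene family),
picks a ~4-tip foreground clade deterministically, and runs the
lineage-vs-average test at α = 0.05 over 200 seeded replicates, with branch
lengths and κ shared from each replicate's Model-0 fit. Because the null
pins the foreground ω to an estimate computed from the same data (dominated
by the background branches), the statistic is stochastically slightly below
χ²₁ and the empirical size runs at or a little below the nominal level —
a property of the average-pinned test construction itself, which the test
suite asserts as "no anti-conservative inflation" rather than exact
equality. Tree depth in both studies is root age 1.0 time unit at rate 0.3
substitutions/codon per unit — root-to-tip divergence of 0.3, typical of an
exon-scale mammalian alignment and deep enough to identify κ and ω without
saturation.

## Synthetic data (`simgen`)

Trees are pure-birth (Yule) with the first split rescaled to a chosen root
age; tips are extant (age 0). Codon states evolve by exact
matrix-exponential transition sampling (a Gillespie jump-chain mode exists
as a validation path), so the 61-state process can never generate a stop
codon and any stop found by the scanner is an injected lesion. Lesions are
applied after substitution, overwriting carrier tips: a nonsense lesion
writes TGA at a codon start (the CpG policy picks a site where every carrier
holds CGA, so the event is a single C→T deamination; no such site is an
error unless a fallback is allowed); deletions gap the carrier bases;
insertions add columns with identical-by-descent bases in carriers and gaps
elsewhere. Origin times are drawn uniformly along the origin branch and
recorded in the truth table together with carrier sets and true parameters.
All randomness flows from one seed; identical seeds give byte-identical
FASTA output.

What the generator does **not** emulate: alignment error (the true alignment
is emitted directly, so scanner tests measure the scanner, not an aligner),
within-species polymorphism and fixation dynamics, sequencing error, rate
variation across sites, and selection-driven codon usage. Passing tests
therefore demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to real-data artifacts such as misalignment
around indels.

## Study fixture (`studydata`)

The printed inputs of the source analysis ship as a deterministic fixture:
the nine felid lesion descriptors with the 18-species presence/absence
matrix, the two extra-felid lesions, the dated Carnivora tree, and the diet
table (30 hypercarnivores, 6 mesocarnivores, 4 hypocarnivores over 40
species). The reference exon is synthetic — a seeded 873 bp open reading
frame carrying CGA at the two documented CpG stop positions — because the
real sequences live in public databases and are not reproduced in print;
every coordinate-dependent computation is exercised against it. Tree ages
that the study prints (felid crown 10.8, felid stem 36.5, Panthera crown
3.7, jaguar split 2.1, domestic-cat/leopard-cat 6.2/6.7, puma/cheetah 4.9,
serval 5.6, brown-hyena split 4.2, elephant-seal/harbor-seal 16) are used
as-is; remaining internal ages are plausible published-era values flagged
`transcribed` in the ages table and are not used by any headline check.
Three otariid species ship with gene status `missing` (amplification
failure), exercising the missing-data path.

## Diet classification (`dietassoc`)

Categories follow the Van Valkenburgh thresholds on percent animal matter:
hypercarnivore > 70, mesocarnivore 50–70, hypocarnivore < 50. Boundaries:
exactly 70 and exactly 50 are mesocarnivore ("more than 70%" and "less than
50%" read strictly) — the sources never test a boundary, so the choice is
documented here. The association with gene status is reported descriptively
(counts plus the check that every pseudogene carrier is a hypercarnivore);
a Fisher exact test on the 2×2 table is available behind a flag as an
extension beyond the descriptive comparison.

## Neighbor joining (`treebuild`)

p and Kimura-2-parameter distances with pairwise deletion (mixed-species
exon panels have ragged ends after trimming, so complete-column deletion
would discard too much). Saitou–Nei NJ with deterministic label-order
tie-breaking; negative branch lengths are clamped to 0 with a warning. On an
additive metric the input distances are reproduced exactly (tested, and
cross-checked against an independent implementation). `assign_identity`
reports the gene label of a query's NJ sister group and flags ties rather
than breaking them silently. Full ML/Bayesian tree inference is out of
scope; published topologies are inputs.

## Pipeline (`pipeline`) and analysis drivers

`run_pipeline` validates a config (YAML-loadable), then runs scan → date →
dnds (optional, per configured foreground lineages) → diet, writing one TSV
per stage plus `summary.tsv` and a `manifest.json` with the seed, config
echo, config hash and library versions; reruns with the same config are
byte-identical. A stage failure raises an error naming the stage and keeps
completed outputs. The `analysis/` scripts are thin numbered drivers over
the library: fixtures, scan, dating, engine calibration (at reduced
replicate counts suitable for an interactive run), diet association.

## Known limitations

* Lesion detection assumes a trusted alignment; there is no re-alignment
  stress mode, and unalignable regions or splice-site/promoter lesions are
  out of scope.
* Whether a lesion is fixed in a population versus polymorphic cannot be
  judged from one sequence per species; "pseudogene" means "this sequence is
  disrupted".
* The codon engine covers Model 0 and branch models only — no site or
  branch-site models, and dN and dS are not reported separately.
* The average-pinned LRT is conservative by construction (see calibration);
  exact size would require a null that accounts for the plug-in estimate.
* Published dN/dS values for the real gene alignments are not reproduced
  here, since the underlying database sequences are external inputs.
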