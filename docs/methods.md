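# Methods

## Scope and model of the data

`woundpep` analyzes label-free peptidomes: per-sample tables of endogenous
peptide sequences with spectral counts (the number of MS/MS spectra matched
to a peptide, used as a semi-quantitative abundance proxy), organized into
labeled groups (e.g. sterile acute wound fluid vs. non-infected vs. infected
wound dressings). The package deliberately starts *after* database
searching: its inputs are identification tables, a protein FASTA, and
optional per-peptide antimicrobial prediction scores. Raw spectra, search
engines and FDR estimation are out of scope.

The analysis chain is:

1. **Ingestion and filtering** (`core_io`). Replicate injections of one
   sample are concatenated by summing per-sequence spectral counts (the
   only table-level operation consistent with pooling spectra before
   search). A spectral-count cutoff (default >= 4) removes low-evidence
   identifications. Modified-residue annotations such as `N(+.98)` are
   stripped with logging rather than rejected, so third-party exports load.
   Group membership is declared in a YAML manifest, never inferred from
   file names.
2. **Localization** (`mapping`). Each peptide is placed in its parent
   protein(s); every overlapping occurrence is reported. Coordinates are
   1-based inclusive. In the per-peptide convention used throughout, P1 is
   the peptide's last residue and P1' its first; a peptide end coinciding
   with the protein's own terminus was not generated by a protease and is
   excluded from cleavage-site statistics. The initiator-methionine policy
   (default on) also treats start position 2 behind an N-terminal Met as
   protein-inherent, because mature proteins frequently lack the initiator.
   Ambiguity default: search the record's declared accessions, falling back
   to the whole database when none are declared; an ambiguous peptide
   contributes its cleavage residues once (spectral count is a per-peptide,
   not per-location, quantity). I and L are kept distinct.
3. **Profiling** (`profiling`). Composition profiles are
   spectral-count-weighted residue frequencies over full sequences or the
   P1/P1' positions; they are compared against a bundled published
   Swiss-Prot composition table (or a reference computed from any FASTA).
   Side-chain classes default to acidic {D,E}, basic {K,R,H},
   polar-uncharged {S,T,N,Q,C,Y}, nonpolar {G,A,V,L,I,P,M,F,W}; the
   grouping is a plain mapping and fully overridable. Terminal tables
   aggregate spectral counts over the 4 proximal residues of either end
   (the MEROPS tetrapeptide convention); protein-inherent termini are
   *retained* here because intact protein termini are themselves biomarker
   candidates; peptides shorter than k are excluded (not padded) and
   counted. Group-level terminal statistics are per-sample aggregates
   summarized as mean +/- sd (ddof = N-1); rank orderings break ties
   lexicographically for reproducibility.
4. **Comparisons** (`comparative`). Exact Venn region partitions for 2-5
   named sets (counts only; drawing is left to plotting tools);
   intersectional peptides = sequences present in every sample of a group;
   differential peptides = top-k by |summed count difference| over the
   union of both groups' intersectional sets (restricting to one group's
   core would drop group-exclusive markers); substrate abundance sums
   counts per parent protein, with multi-protein peptides contributing
   their full count to each distinct accession (double-counted mass is
   reported) and an exclusion list for dominating proteins; occurrence
   outliers flag high-count sequences seen in exactly one sample. Group
   means are compared with Welch's t by default — group sizes are unequal
   and no natural pairing exists across patients — with a paired Student t
   available; zero-variance paired differences are flagged degenerate
   rather than silently returning a number.
5. **Protease attribution** (`comparative`). A deliberately simple,
   deterministic presence/absence rule over P1 (optionally P1') residue
   sets per protease. It makes no claim of equivalence to database-driven
   cleavage-site predictors; it answers only "which of these specificity
   patterns is compatible with the observed cleavage events, and how
   often".
6. **Antimicrobial scoring and regions** (`amp_region`). The antimicrobial
   score of a peptide in a sample is prediction x spectral count; peptides
   with prediction below the cutoff (default 0.7; the boundary value 0.70
   is *kept*, matching a "below 0.7 is discarded" rule) are removed, and
   group totals sum the surviving peptides' spectral counts. Peptides
   longer than 30 residues fall outside the domain of short-AMP predictors
   and are excluded with a report. The built-in scorer is a frozen logistic
   over net charge z = (#K + #R + 0.5#H) - (#D + #E) and hydrophobic
   fraction h: score = 1/(1+exp(-(0.5z + 4h - 3))). It is plumbing so the
   pipeline runs without an external predictor; its absolute values carry
   no biological meaning and are never compared against any published
   predictor's output. Coverage profiles give per-residue distinct-peptide
   counts and summed spectral counts along a protein (the data behind
   peptide-alignment visualizations); region sums confine spectral counting
   to a stated region (confined = fully inside; overlapping = any overlap),
   with exact-match totals for listed reference peptides. Literature
   matching is exact-substring in either direction; no edit distance.

## The synthetic-data generator

`synthetic` generates grouped peptidomes with full ground truth so that
every stage is testable without clinical data.

**Generative model.** Per sample: substrate proteins are drawn by relative
abundance; each candidate cleavage site is cut independently with
probability proportional to the planted P1 propensity of the residue
N-terminal of the cut, normalized per residue type and scaled to one cut
per ~12 residues (so the realized cut set's P1 composition equals the
planted distribution restricted to the residues the protein contains);
fragments form between successive cuts (protein-terminal fragments
included); each end may be trimmed geometrically (exopeptidase model,
parameter `exo_trim_prob` per end); lengths outside `length_bounds`
(default 4-45; minimum 4 so terminal 4-mers exist) are discarded. Each
unique fragment receives one negative-binomial spectral count
(mean 1.3, dispersion 1.0 by default — overdispersed, with roughly a fifth
to a third of observed peptides passing the >= 4 cutoff, and a draw of 0
meaning the fragment went undetected). Seeding fans out per
(group, sample), so adding samples never perturbs earlier ones, and equal
seeds give byte-identical tables.

**Identifiability guarantees** (what makes the ground truth an exact
oracle): planted core peptides enter every sample of their group with a
count at or above the default cutoff, and any non-core peptide that would
by chance occur in all samples of a group is withheld from one
pseudo-randomly chosen sample. Group intersections therefore recover the
planted cores exactly. This withholding is a property of the oracle design,
not of real peptidomes, and can be disabled (`identifiable_cores=False`),
which restores strict sample-addition stability.

**The default study** (`study_design`): three groups of three samples.
`acute` has uniform P1 propensities; `non_infected` and `infected` plant an
acidic-biased cleavage preference (D+E carry 0.40 of the P1 mass),
emulating a bacterial-protease-like signature. The infected group
additionally gets a raised hemoglobin-region substrate weight and an
abundance hotspot (count mean x 10) confined to the C-terminal
hemoglobin-beta toy region — a planted analogue of infection-associated
hemoglobin degradation. Exo-trimming is disabled in this design: trimming
overwrites cut-site residues by construction, so recovery of a planted
cleavage preference is only well-posed without it. Filler proteins
(pseudo-random, Swiss-Prot-like composition, 48 x 600 residues by default)
dominate the substrate mix for two reasons: realism (a complex background
proteome) and estimator integrity — the miniature documented-region toy
proteins lack some residues, and if they dominated, the renormalized
per-protein cut distributions would distort the planted P1 marginal. The
proteome is also kept much larger than the per-sample peptide demand so
that the unique-fragment pool does not saturate (saturation
under-represents frequently regenerated fragments and biases the recovered
cleavage preference — a species-sampling effect, not a property of the
digestion model).

**What the generator does not emulate:** retention time, charge states,
spectra, missed-cleavage chemistry beyond the per-site propensity,
inter-sample batch effects, and shared peptides between homologous
proteins (each fragment has a unique recorded origin). Passing recovery
tests therefore demonstrates correctness of the analysis arithmetic and
estimator consistency under the stated model — not performance on clinical
LC-MS/MS data.

## Numerical choices

- Standard deviations use ddof = N-1 throughout.
- Composition profiles must normalize to 1 within 1e-9.
- Monoisotopic peptide masses (residues + water) in Da.
- Sorting ties (rank tables, differential peptides, substrate rankings)
  break lexicographically so outputs are deterministic.
- The AMP cutoff keeps predictions exactly equal to the cutoff value.
- Degenerate statistics (zero-variance paired differences, empty groups,
  zero-weight profiles) return explicit flags/nulls, never silent numbers.

## Problem sizes used in validation

The validation suite simulates the default study at 2,500 peptides per
sample (nine samples, ~25,000 peptide observations) — large enough that the
planted acidic P1 share (0.40) is recovered within +/-2 percentage points
and the planted hotspot exceeds control groups' region sums by far more
than threefold, while the whole suite runs in seconds. Oracle-equivalence
checks run on hundreds to a thousand randomized instances per operation
(exact Venn partitions vs. a membership-bitmask tally, localization vs. a
brute-force substring scan, coverage vs. a per-position scan, Welch/paired
t vs. closed-form formulas at 1e-10).

## Known limitations

- The protease attribution and the built-in antimicrobial scorer are
  intentionally simplistic stand-ins for database-driven tools; their
  outputs support pipeline plumbing and simulation recovery tests, not
  biological inference.
- Region numbering follows whatever coordinate convention the caller's
  FASTA uses (with vs. without initiator Met); region bounds are user
  input and the package does not adjudicate between conventions.
- Spectral counting is semi-quantitative; all between-group statements are
  comparative, not absolute abundances.
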