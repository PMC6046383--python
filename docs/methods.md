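# Methods

This note documents the models, defaults and design choices behind
`netomix`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Digestion and observability

Trypsin cleaves C-terminal to K or R except when the next residue is
proline (the Mascot-style rule; the ExPASy rule's rare WKP/MRP exceptions
are deliberately not applied). Peptides carry 1-based inclusive precursor
coordinates with the initiator methionine retained, so residue numbers
match UniProt precursor numbering. Up to 2 missed cleavages are generated
by default.

A peptide is *observable* when its length is 6–40 residues and at least
one charge state z ∈ {2, 3} puts (M + z·1.00728)/z inside the 350–1,600
m/z scan window. Monoisotopic masses are residue-mass sums plus one water
(via pyteomics). `N_obsbl` counts unique observable peptide sequences up
to the same missed-cleavage limit used for matching, keeping the emPAI
numerator and denominator populations consistent. These four knobs
(length bounds, m/z bounds, charges, missed cleavages) are configuration;
search engines use their own internal observability heuristics, so
absolute emPAI values are comparable only within a fixed configuration.

## Identification

Decoys are reversed target sequences with a reserved accession prefix —
deterministic, and length-preserving so the decoy score distribution is a
fair null. The FDR statistic 2·Md/(Md+Mt) estimates the fraction of false
matches in a score-ranked prefix under the assumption that false matches
hit the target and decoy halves of the database equally often. Filtering
is protein-level: protein score is the summed PSM score (max-score is a
config alternative), ties break lexicographically by accession for
determinism, and the retained set is the largest prefix whose running FDR
stays at or below the threshold. The threshold "FDR ≤ 1" is interpreted
as 1 **percent**: as a fraction, a cutoff of 1 would retain everything
(the statistic only reaches 1 when decoys equal targets), and 1 % is the
field-standard protein-level cutoff. The peptide-score > 20 filter is
applied strictly (> not ≥) and, by default, only where peptide-level
evidence is displayed (peptigrams, peptide absence calls), not during
protein identification; a config switch moves it upstream.

## Quantification

`N_obsd` counts unique peptide sequences per protein per sample.
Modification labels (oxidation, deamidation) are annotations in a
separate column, so a peptide observed with and without a modification
counts once; a switch makes modified forms distinct. Charge states never
split a peptide. Peptides shared between retained proteins count toward
every protein they match — subtype-level accessions (e.g. histone H2B
subtypes) are quantified separately and summed later at the group level,
so razor-protein collapsing would discard exactly the structure the
differential analysis needs. PAI is not clamped at 1: a protein matched
by more peptides than the window deems observable is legal and simply has
PAI > 1.

## NETome definition

Within each (donor, treatment) pair the −DNase emPAI is subtracted from
the +DNase emPAI and clamped at zero — a negative "NET-bound abundance"
is meaningless; the −DNase arm is a background to eliminate, not a signed
signal. A protein absent from an arm contributes zero there, but a
missing −DNase arm is an error (the subtraction is undefined without its
background). The consensus rule (NET-bound in ≥ 2 of 3 donors) is a
majority vote: it tolerates one donor dropout while preventing a single
noisy donor from admitting a protein. Donor reproducibility is summarised
by Pearson correlation of log10(emPAI + 0.01) over the union of proteins
in each (treatment, DNase) stratum; emPAI is heavy-tailed and
multiplicative, so raw-scale Pearson would be dominated by the few most
abundant proteins (raw and Spearman variants are available).

## Differential analysis

Donor-matched ratios are computed on raw +DNase emPAI (not
background-subtracted values): the ratio asks how a protein's *release*
changed under treatment, and dividing two subtracted quantities would
compound two noisy differences. Donors whose untreated control is zero
are excluded from that group's test and flagged. The one-way ANOVA and
Dunnett many-to-one comparisons run on the ratios; significance codes
follow the GraphPad convention (# p<0.1 ns, * p<0.05, ** p<0.01,
*** p<0.001, **** p<0.0001). scipy's Dunnett implementation integrates a
multivariate t by quasi-Monte Carlo; the integration rng is fixed so
pipeline reruns are byte-identical (p-values are stable to ~1e-4).

Hierarchical clustering operates on the protein × treatment matrix of
donor-averaged net emPAI, z-scored per row so profiles cluster by shape
rather than magnitude, with Euclidean distance and average linkage.
Eight clusters are requested by default; all parameters are
configuration. Cluster ids are renumbered along the dendrogram leaf
order, making the labelling deterministic.

## Peptigrams

Track values are summed scores (not counts): repeated detections of the
same peptide add up, so track height reflects both coverage and evidence
strength. Missing regions are maximal runs of residues covered in the
reference track and empty in the comparison track; by construction
reported regions are disjoint and never adjacent. Peptide-level absence
calls keep donors separate: a peptide is reported when it passes the
score filter in the control of ≥ 1 donor and has no passing PSM in ≥ 2
donors of a treated condition. Whether to pool donors into one display
track is left to the caller (pooling is summation, which the additivity
of tracks makes well-defined).

## The synthetic experiment

The generator emulates the study design the analysis assumes: 3 donors ×
3 treatments × ±DNase, with technical duplicate injections per sample.
Its defaults are the package's declared study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_net_proteins` / `n_background_proteins` | 100 / 50 | planted NET-bound vs constitutively released proteins |
| `protein_length_range` | 200–500 aa | gives ~25–90 observable peptides per protein |
| `base_detect_prob` | 0.5 | per-peptide detection probability of an average NET protein |
| `background_release_prob` | 0.7 | same, for background proteins (both DNase arms) |
| `high_abundance_detect_prob` | 0.995 | fixture (histone/elastase-like) proteins; these are the most abundant proteins in a NET sample |
| `protease_effect` | 0.4 | multiplier on detection **odds** under thrombin/plasmin for sensitive proteins |
| `protease_sensitive_fraction` | 0.3 | fraction of NET proteins that respond to the proteases |
| `protein_abundance_sd` | 1.5 | log-odds SD of per-protein abundance (shared across donors) |
| `donor_noise_sd` | 0.15 | log-odds SD of per-(donor, protein) jitter |
| `run_dropout` | 0.03 | per-run miss probability for a detectable peptide |
| `n_technical_replicates` | 2 | injections per sample; detected replicates each yield a PSM |
| `decoy_match_rate` | 25 | expected decoy PSMs per sample (Poisson) |
| scores | 15 + Γ(2, 8); fixtures 15 + Γ(4, 10); decoys 15 + Γ(1, 3) | shifted-gamma peptide scores; a realistic fraction falls below the 20 threshold |

Detection is Bernoulli per observable peptide with odds = class base odds
× protein abundance × donor jitter (× protease effect where applicable),
which ties the abundance model directly to emPAI. For a *background*
protein the latent per-(donor, peptide) detectability is shared between
the two DNase arms — within a donor both arms sample the same
conditioned medium — with only the per-run dropout differing between
arms. The abundance and jitter SDs and the run dropout were calibrated
in a pilot so the simulated experiment reproduces the reproducibility a
real donor-matched NET experiment shows (between-donor correlations
above ~0.8) while the zero-margin subtraction filter admits background
only rarely; with fully independent per-arm detection noise a zero-margin
filter would leak badly (see limitations).

NET-class proteins never emit PSMs in −DNase samples (the construction
rule the subtraction filter assumes). Planted deletions suppress every
PSM overlapping the region in the listed treatments: the histone H4
fixture (the real 103-residue precursor sequence) loses residues 61–78 —
the span of the tryptic peptide VFLENVIRDAVTYTEHAK — under both
proteases, and a synthetic elastase-like fixture loses four designed
tryptic peptides. The elastase-like sequence is built from tryptic
blocks sized so that the four deletion peptides have no other observable
peptide overlapping them (flanking fragments are long enough that any
missed-cleavage variant exceeds the 40-residue observability bound),
which makes the peptide-level absence report exactly the planted set.

**What passing tests do not show.** Real DDA data differ from this
generator in ways that matter: run-to-run peptide overlap between
technical replicates is far lower (~70–80 %) than the 3 % dropout
modelled here, so on real data a zero-margin subtraction relies much more
heavily on the donor-consensus vote; search-engine scores correlate with
peptide properties rather than being i.i.d.; false target matches occur
alongside decoy matches (modelled in the dedicated FDR calibration
experiment, not in the main generator); and chimeric/one-hit-wonder
identifications, retention-time effects and protein inference ambiguity
are absent. Recovery rates measured here characterise the pipeline's
logic, not its field performance.

## Numerical choices and degenerate inputs

emPAI is exact closed-form; no tolerance is involved beyond float
arithmetic (the mass calculation is stable to 1e-4 Da). A protein whose
observability window admits no peptides cannot be quantified and is
reported with NaN abundances rather than dropped silently. Empty PSM
tables are errors for identification and no-ops for the score filter.
All-degenerate Dunnett input (every group constant) is an error; a
constant control group alone (ratios exactly 1 by construction) is legal.
Constant rows in the clustering matrix z-score to zero. Problem sizes in
the test suite and acceptance script (150-protein proteomes, a
1,000-protein FDR calibration, 2,000 Dunnett null datasets) were chosen
to keep the full validation run in well under half an hour on one core
while leaving every estimate's Monte-Carlo error small relative to the
bands being checked.

## Known limitations

* Protein inference is single-accession per PSM row; grouping of
  indistinguishable proteins is out of scope (subtype aggregation is
  explicit, by configured accession lists).
* The observability window is a declared approximation of instrument
  behaviour, not a model of any search engine's internal emPAI
  computation.
* The peptigram module reports presence/absence against a hard score
  threshold; it does not model censoring (a peptide just under threshold
  counts as absent).
* The pipeline is single-process and in-memory; PSM tables of tens of
  millions of rows would need chunked IO.
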