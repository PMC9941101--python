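# Methods

## Problem and scope

Ribosomal RNA carries dozens of 2′-O-methyl (Nm) and pseudouridine (Ψ)
marks placed by C/D-box and H/ACA-box snoRNPs. Many are sub-stoichiometric —
only a fraction of the ribosome population is modified at a site — and that
fraction shifts with cell state and with perturbations of the guide-snoRNA
pool. `ribomod` quantifies those fractions from read-end count profiles of
two cleavage-protection chemistries, tests them between conditions, and asks
whether the changes track the expression of the sites' guide snoRNAs.

The package does not process raw reads. Its inputs are per-position 5′/3′
read-end counts (one TSV per replicate), a reference FASTA, a site catalog,
and optionally a snoRNA differential-expression export. A built-in simulator
produces end-count profiles with known ground truth so every downstream
stage is testable without sequencing data.

## The cleavage model

Both chemistries are modelled as independent Poisson cleavage events.

**Alkaline hydrolysis (RMS).** Every phosphodiester bond is attacked with a
uniform propensity under denaturing alkaline conditions. A 2′-O-methyl on
nucleotide *j* blocks attack on its own 3′ bond, so bond *j* receives
expected intensity

    λ_j = depth · base_rate · (1 − f_j · (1 − residual))

where `f_j ∈ [0, 1]` is the methylated fraction and `residual` (default 0)
the relative propensity a fully modified site retains. Each event leaves a
3′ read end at *j* and a 5′ read end at *j + 1*. An optional fragment mode
draws whole fragments bounded by two cuts 20–40 nt apart (the library's
size-selection window, uniform acceptance) and exists to exercise end-count
conservation; its effect on local count ratios is assumed negligible.

**Hydrazine/aniline (HydraPsi).** Only uridines are appreciably reactive;
pseudouridine resists. A uridine receives the same protected intensity with
`f_i` the pseudouridylated fraction; non-U residues retain a small relative
propensity `bg_rate` (default 0.01). Each event leaves a 5′ end at the
cleaved U shifted by `end_offset` (default 0; real-data users mapping read
starts one base downstream can set +1 — the simulator and scorer share the
setting, so the pair stays consistent).

Why Poisson events instead of molecule-by-molecule simulation: the scorers
consume local count *ratios*, for which only per-bond expected intensities
and independent counting noise matter; the event model reproduces exactly
that and keeps 200-simulation calibration runs cheap. Replicate noise is
purely Poisson — no overdispersion parameter in this version — so the
replicate scatter of real libraries is, if anything, underestimated.
Replicate *r* of a run with seed *s* draws from the independent stream
`default_rng([s, r])`; adding replicates never changes earlier ones.

## MethScore

Cleavage evidence per bond combines both ends a cut produces,
`c_j = counts3[j] + counts5[j+1]`, making the track robust to one-sided end
losses. A site at nucleotide *i* maps to bond *i* (the methyl protects its
own 3′ bond — the simulator mirrors the same attribution). With L̄ and R̄
the means of up to six flanking bonds per side,

    MethScore_i = clip(1 − 2 c_i / (L̄ + R̄), 0, 1).

In expectation this equals `f_i` when the flanks are cleaved at the
background rate. Conventions:

* **Undefined, never zero.** Fewer than three usable bonds on a side, or a
  zero flanking background, yields a missing score — a molecule end must not
  read as "unmethylated". Missing scores are excluded from condition means
  with a warning.
* **Clipping.** Raw values below 0 (hyper-cleavage) are floored; reported
  scores live in [0, 1], matching the fraction interpretation.
* **No masking of annotated neighbours.** Flanking windows are not purged of
  other catalog sites; at clusters of sub-stoichiometric sites this biases
  scores upward slightly. The packaged fixture spaces unnamed sites ≥ 13 nt
  apart so the bias does not touch the validated sites.
* The weighted-window variants of the original scoring family are not
  reproduced (their weights are not restated in the sources available to
  this package); output metadata labels the score `symmetric-flank-mean`.

At `depth · base_rate = 2000` per bond the single-replicate sampling error
is ≈ `1/√2000` ≈ 0.022, and the measured bias across the stoichiometry grid
{0, 0.25, 0.5, 0.75, 1} stays below 0.03 (the null mean at f = 0 is ≈ +0.013,
the price of flooring at zero).

## NormUcount and PsiScore

1. `rolling_background`: a plain mean of the 5′-end counts over a 10-nt
   window, centre-right for the even default (positions `i−5 … i+4`),
   shrinking at molecule ends; missing where fewer than `window/2` positions
   remain or the mean is zero. By default the window *includes* the queried
   position — the simplest reading of local-background normalisation — and
   `exclude_self=True` switches to the leave-one-out mean. The two differ at
   strongly protected sites (a fully protected U depresses its own
   background by 1/window), so the mode is recorded in output metadata;
   recovery validation uses leave-one-out.
2. `NormUcount = counts5[i] / background[i]` — the protection value.
3. The profile is restricted to U residues (original coordinates kept), and

       PsiScore_i = 1 − NormUcount_i.

   Bounded above by 1, *not* floored below: a negative score means the
   residue is cleaved above its local background, i.e. it is not
   pseudouridylated; strongly negative values flag hyper-reactive residues.

**Calibration assumption.** `PsiScore ≈ f` requires the window background to
be dominated by unmodified-U cleavage. Where non-U neighbours (carrying only
`bg_rate`-level counts) dilute the background, every score in that window
shifts downward by a composition-dependent amount — which is also why
unprotected residues in pyrimidine-poor contexts print scores like −3 rather
than 0. The packaged fixture therefore embeds every Ψ site in a ±7-nt
uridine context, and the recovery/null property tests run on all-U
substrates; a passing suite demonstrates correct protection arithmetic, not
composition-independence on arbitrary real profiles. The recovery bound
(|bias| < 0.04 over f ∈ {0, 0.3, 0.6, 0.9}) additionally assumes ≤ 20 % of
window positions are themselves modified, since modified neighbours depress
the background and deflate the score.

`scoremean`, the auxiliary diagnostic, applies the MethScore-shaped flanking
ratio to the nearest six defined U neighbours per side (clipped only from
above). Other auxiliary scores of the original protocol family are not
reproduced; PsiScore is the primary output.

## Differential calling

Scores are aggregated per condition over defined replicates; each site is
tested with a paired Student's t-test on within-pair differences (pairing by
replicate/batch label — the only pairing key the design provides), df = n−1,
two-sided p. The statistic is computed from its closed form; SciPy supplies
only the t distribution. Degenerate cases: all differences zero → p = 1;
zero variance with non-zero mean → p reported as the 0-limit and flagged.
Sites need ≥ 2 complete pairs; exactly 2 runs at df = 1 and is inherently
low-powered.

Classification uses two deliberately distinct thresholds: `affected` when
|Δ| > 0.05 (strict), `heatmap`-eligible when |Δ| ≥ 0.1 (inclusive); |Δ| is
rounded to 9 decimals first so the boundaries behave like exact arithmetic.
Direction is the sign of Δ for affected sites. Stars follow the raw p
(≤ 0.05 / 0.01 / 0.001); no multiple-testing correction drives any call — a
Benjamini–Hochberg column is emitted for reference only, matching the
raw-p reporting convention of the field's tables. An unpaired fallback is
deliberately absent from the calls; the paired test is the contract.

Calibration (regenerated by the test suite): type-I error on equal-truth
simulations is 0.05 within a 3-SE binomial interval over 1000 site
simulations; a 0.3 stoichiometry shift at depth·base_rate = 2000 with n = 3
is detected at p ≤ 0.05 in > 90 % of 200 simulations.

## Guide concordance

The snoRNA differential-expression table is consumed, never computed (it is
a routine DESeq2/qPCR product upstream of this package). A guide counts as
changed when any evidence source reports padj ≤ 0.05 with |log2FC| above the
fold-change threshold (default 0 — direction, not magnitude, is read;
`strict` mode requires all sources for a guide to agree). Verdicts partition
the sites: `concordant` (≥ 1 significant co-directional guide, none
opposing — a two-guide site where only one guide responds is concordant),
`partial` (significant guides disagree), `discordant` (every significant
guide opposes, *including* the vacuous case of a changed site with no
significant guide change — the five-way partition has no separate slot for
"unsupported", and silence is treated as failure to support), `no_guide`
(orphan site), `site_unchanged`.

## Fixtures and demo conditions

The packaged fixture set is generated in code from a fixed internal seed:
synthetic 18S (1869 nt), 28S (5070 nt) and 5.8S (157 nt) molecules; an Nm
catalog of 41/67/2 sites and a Ψ catalog of 44/61/2 sites, with the named
FUS-responsive sites, their guides, and the (non-arithmetic) legacy 28S
numbering carried as data. Unnamed catalog sites sit ≥ 13 nt from all
others. Demo ground truths place the published wild-type vs FUS-knockout
stoichiometries at the named sites (e.g. 18S-Um354 0.02 → 0.31, 18S-Cm1272
0.39 → 0.60, 28S-Psi1779 0.75 → 0.92) and a near-saturated default (0.95 Nm,
0.90 Ψ) elsewhere; 28S-Psi2843, an unprotected residue in vivo, is modelled
as f = 0 because hyper-reactivity (`residual > 1`) is outside the protection
model's parameter domain. The demo snoRNA DE table is fabricated with
co-directional significant guides at the responsive sites, including the
two-guide/one-responder pattern.

What the fixture does **not** emulate: replicate overdispersion, ligation
and end biases, coverage trends along the molecule, mixed-composition Ψ
neighbourhoods (see calibration assumption above), and terminal-fragment
artefacts. Passing tests therefore validate the estimators and the decision
logic under their stated assumptions, not pipeline performance on raw
sequencing data.

Default problem sizes — depth·base_rate 20000/bond (RMS) and 5000/U
(HydraPsi), 3 replicates, 50-simulation bias grids, 200-simulation null and
power runs, 1000-simulation type-I runs — were chosen so that sampling error
is several-fold smaller than the tolerances being checked while a full
validation sweep stays in the seconds-to-minutes range on one core.

## Numerical conventions

* Coordinates are 1-based inclusive everywhere except the BEDGraph export
  (0-based half-open, flagged in the writer).
* U/T are equivalent on input; the canonical alphabet is {A, C, G, U, N}.
* Missing is always distinct from zero (NaN in tables, `None` in the API).
* Every output table carries the package version, effective master seed and
  a digest of the scientific parameters (paths excluded), plus the formula
  variants in effect, so any two runs are comparable.
* Sub-seeds for simulation streams are derived with `numpy.random.SeedSequence`
  from the master seed and stage indices; all stay below 2³¹.
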