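# Methods

## Scope

`crisscut` simulates the scission of a crisscross DNA ribbon by invader
("cut") slats at the site-graph level, and separately simulates population
amplification with a coarse growth/cut model.  Growth of new ribbon repeats
at the site-graph level, nucleotide sequences, thermodynamics, and spatial
(off-lattice) dynamics are out of scope.

## Site-graph model

### Topology

A ribbon is a stagger-1 parallelogram of growth slats: `X_i` (i = 1..N,
N = R·L, R repeats of L slats) and `Y_j` (j = 1..N+L−1), with a bond
`(X_i, Y_j)` whenever `0 ≤ j − i ≤ L − 1`.  Any stagger-1 crisscross
lattice is equivalent at the site-graph level, so this one convention makes
every count well defined.  Pruning is single-pass: the two lattice-edge y
slats with fewer than two bonds in the full lattice (`Y_1`, `Y_{N+L−1}`)
are removed together with their bonds.  (An iterative prune would cascade
through the whole lattice at L = 2.)

Slats with index ≤ N/2 form half A, the rest half B.  The bonds joining the
halves — L(L−1)/2 of them for R = 2 — are the cut interface, and scission
ground truth is their joint absence: the first time no complex contains
growth slats of both halves.

### Cut slats

One `CUT_Y_j` type exists per B-half y slat holding interface bonds (it
displaces that slat's grip on half A and caps half A), and symmetrically
one `CUT_X_i` per A-half x slat (capping half B).  A cut type carries:

* one *competed* site per interface bond it invades, compatible with the
  same growth-slat core site the incumbent uses — mutual exclusion is
  automatic because a site holds at most one bond;
* E *toehold* sites, each compatible with a dedicated *extension-host*
  site on a slat of the half it caps.  Host windows sit adjacent to the
  competed range and are clamped inside the capping half; when E exceeds
  the half's slat span the window wraps, i.e. a slat may carry several
  extension segments.  Keeping the anchors inside the capping half is what
  lets a completed displacement actually sever the ribbon.

Branch migration is not modelled at base-pair resolution; it emerges as
site-by-site (half-turn) unbind/rebind competition, with the toehold
anchors holding the invader in place between steps.

### Rates

Time is measured in growth-bond lifetimes (off-rate 1).  Defaults:

| parameter | standard | prebound | meaning |
|---|---|---|---|
| k_off | 1 | 0.8 | every bond's off-rate |
| k_on_inter | 0.04 | 0.05 | free monomer binding a complex, per copy |
| k_on_intra | 40 | 50 | bond formation inside one complex |
| α = intra/inter | 1000 | 1000 | positional-entropy penalty of capture |
| cut_excess | 100 | 100 | free copies per cut-slat type |
| wobble on/off factors | 2/3, 1.5 | 2/3, 1.5 | growth-side scaling at wobble bonds |

Copy number stands in for concentration: an intercomplex binding candidate
has propensity `k_on_inter × copies`, and α is defined at one copy.  The
prebound parameterization starts one copy of every cut type bound by all
its toeholds, and its intracomplex on-rate is derived as
α × k_on_inter(prebound) = 50, keeping α the governing ratio.

Wobble factors apply only to growth–growth bonds at the designated
positions, never to cut-slat bonds.  This asymmetry — weakened incumbent,
normal invader — is the kinetic ratchet.

### Locality constraint

Two slats of one complex may form a new bond only if the current bond graph
connects them through at most two intermediate slats (path of ≤ 3 bonds).
This is the standard graph surrogate for physical proximity in rule-based
models of assemblies, and it is also what makes displacement ratchet
forward: once a displaced slat has lost enough bonds, distant re-binding
becomes ineligible.

Intercomplex binding is restricted to free monomer ↔ complex; two
multi-slat complexes never join (the system of interest is one ribbon plus
free slats).  A slat whose last bond breaks returns to the free pool and
may rebind at intercomplex rates; a flag (`recycle_displaced=False`)
deletes such slats instead, for comparison.

### Engine

The simulation is an exact Gillespie algorithm.  Candidates are grouped by
propensity coefficient, so one event costs O(#groups) for selection plus a
local update: after each event only candidates touching the affected
slats' neighbourhoods are recomputed, and locality re-checks are restricted
to watch pairs whose endpoints lie within two bonds of the toggled edge
(any path of ≤ 3 bonds through that edge has both endpoints there).
Complex splits are detected by a cheap reconnection test (the broken pair
almost always stays within 3 bonds) with a full traversal as fallback.
Running totals are resynchronized every 4096 events to bound floating-point
drift.

`audit` mode asserts, per event, site occupancy and exact per-type copy
conservation, re-checks locality on every applied intracomplex bind, and at
a configurable stride rebuilds the entire candidate set from scratch and
requires equality with the incrementally maintained one.

Determinism: a replicate is a pure function of (model, mode, seed); one
`random.Random(seed)` drives all draws, and ensembles use seeds
`base_seed + replicate`.

### Scission detection

* `half_label` (primary, exact): first time no complex contains both
  halves, recorded online with the growth-slat counts of the two largest
  complexes at that moment.
* `size_drop` (secondary, what one would read off a plot): first sample at
  which the largest complex is ≤ 70 % of its running maximum.  The 30 %
  threshold is arbitrary, which is precisely why the half-label method is
  the ground truth; both are reported, and agreement is quantified as
  pointing at the same or adjacent recorded complex-structure change.
* "Comparable products" means both post-scission products hold ≥ 25 % of
  the initial growth slats.
* Replicates that hit `t_max` or `event_max` are censored; means are over
  detected scissions only and censoring is always reported, never imputed.

### Wobble layouts

Sweep utilities restrict wobbles to cross-interface bonds — in a
growth-free scission simulation, wobbles elsewhere cannot change the
outcome.  Named arrangements: `terminal` (default), `front_spread`,
`front_block`, `uniform`.

The default placement deserves explanation.  Displacement by each cut slat
initiates at its toehold-proximal end and terminates at the deep interior
corner of the interface; the corner bonds are displaced last and re-zip
most easily, so they gate scission.  A placement screen (prebound mode,
400 replicates per condition, matched seeds) was consistent with this:
wobbles at or along the terminal edges showed the largest speed-ups, while
five wobbles spread along the initiation diagonal showed essentially none —
the initiation front is displaced easily with or without help.  The
`terminal` arrangement was therefore adopted as the default, the same
empirical placement-screening logic used when designing real wobble
layouts.  A definitive 1600-replicate-per-condition comparison puts the
terminal-wobble effect at 0.152 ± 0.060 time units, i.e. ≈2.3 % of the
mean scission time (6.53 ± 0.04 without wobbles, 6.38 ± 0.04 with).  The
effect of five wobbles at strength 2/3 is thus real but intrinsically
small in this model: resolving it at two standard errors needs on the
order of a thousand replicates per condition, and ensembles of 300 will
typically show the direction but not a 2-SE separation.

## Exact CTMC oracle

For models with one copy per slat type the state space (a set of bonds;
pools follow from bondlessness) is enumerable.  `crisscut.ctmc` re-derives
the transition structure directly from the model definition — independent
of the engine's incremental machinery — makes scission states absorbing,
and solves the linear first-step equations for the exact mean first-passage
time.  The toy used in tests (L = 2, R = 2, E = 1, cut-y only, one copy)
has 64 transient states and a closed-form answer: its single interface bond
severs the halves the moment it first breaks, so the mean scission time is
exactly 1/k_off (and 1/(1.5·k_off) when that bond is a wobble).  The
Gillespie engine must reproduce this within Monte Carlo error, which
validates waiting times, event selection and state updates end to end.

## Coarse growth/cut model

Each ribbon grows at rate v at one growing end.  A cut site exists at every
multiple of Δ of material; its exponential clock (hazard λ) starts when the
ribbon first grows past `site + Δ`, i.e. when the repeat distal to the
interface is complete and can recruit cut slats.  A firing splits the
ribbon; the proximal fragment gains a fresh growth front, both children
inherit the armed clocks of their material (memoryless, so exact), and a
freshly cut junction re-arms only after a full new repeat grows past it.

Consequences, used as test oracles: λ = 0 gives a single ribbon of length
exactly ℓ₀ + v·t; λ → ∞ gives exact binary fission — every fragment born
at length Δ, splitting at 2Δ, count doubling every Δ/v — which is the
idealized doubling of the growth/scission chain reaction; mass is conserved
exactly at every cut (children sum to the parent, to floating-point
rounding) and total mass equals v × the time integral of the ribbon count.
The simulation is event-driven (heap of arm/fire events, lazy invalidation
after splits) and exact; monomer depletion is deliberately not modelled, so
there is no late-time plateau.

## Kappa export

`export_kappa` writes the model as a KaSim-4-dialect document: one agent
per slat type, one unbinding and one intercomplex binding rule per
compatible site pair, and one intracomplex binding rule per (pair, bonded
traversal) where the traversal — a simple path of ≤ 3 bonds over the
type-level potential-bond graph, no slat type revisited, no site reused
within an agent — encodes the locality context in the rule's left-hand
side.  Rates are the engine's propensity coefficients (the intercomplex
coefficient is per monomer copy).  The bundled reader validates syntax and
counts and preserves patterns verbatim, so export → parse → render is a
byte-identical fixed point.  Running KaSim itself is never required.

## What the synthetic conditions do and do not show

All studies are on programmatically generated ribbons with two repeats and
idealized, sequence-free kinetics: identical off-rates everywhere (except
designated wobbles), a single α for all capture events, and copy numbers in
place of concentrations.  Passing tests therefore demonstrate internal
correctness (exact stochastic simulation of the stated model) and
qualitative design trends — scission slows with ribbon width, wobble
ratchets accelerate it, amplification doubles per repeat in the fast-cut
limit.  They do not calibrate absolute time scales, sequence-dependent
asymmetries (e.g. cut-x versus cut-y efficiency differences seen in real
designs), cooperative recruitment, or monomer depletion.

## Problem sizes

Default study sizes were chosen to keep full reproduction in the
few-minute range on one CPU: 100 replicates per standard-mode condition,
300 per prebound wobble condition, 10,000 replicates against the exact
CTMC value, and coarse-model runs to ~2,000 fragments.  A default L = 10
run takes ~4,000 events (~0.1 s).
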