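# Methods

This note records the models, rules, parameters and numerical choices the
package implements, and what its synthetic data do and do not emulate.

## Density maps and thresholds

A map is a 3D scalar grid with per-axis voxel size and an Å origin; the
index↔coordinate transform is affine and invertible. Every σ-threshold in
the package means `avgD + k·σ` where `avgD` and `σ` are the mean and
standard deviation over **all** voxels of the relevant map — no solvent
mask or flattening is applied first. Density *values* are always obtained
by trilinear interpolation.

Segmentation is a watershed of the super-threshold region: each voxel
follows steepest ascent among its 26 neighbors, and voxels whose paths
end at the same local maximum form one segment. Ties in ascent direction
go to the lowest linear voxel index, which makes the labeling fully
deterministic; segments are visited by decreasing volume. Within each
segment the peak (`Pmax`) is refined by gradient ascent (initial step 0.1
voxel, halved on non-improving proposals, stop below 1e−4 Å or 1000
steps) on a **cubic-spline** interpolant of the grid. A trilinear field
attains its maxima exactly at voxel centers, so ascent on it cannot
localize a peak off-grid; the spline field is the minimal C1 surrogate
that can. Peak *density* at `Pmax` is still read trilinearly.

Simulated maps place an isotropic Gaussian of standard deviation
`sd = resolution/(π√2) ≈ 0.225·resolution` on each heavy atom — the
common map-from-model convention — with peak amplitude equal to the
species weight (water 1.0, Mg²⁺ 1.5, Na⁺ 1.3, RNA 1.0). Amplitudes are
not scaled by atomic number by default; both the width factor and the
weights are arguments.

## Q-score

Q is the Pearson correlation between map values sampled on concentric
shells around the query point (radius 0 to 2.0 Å in 0.1 Å steps, 8
deterministic Fibonacci-sphere points per shell, a per-shell phase
decorrelating the shells) and the reference profile
`g(r) = A·exp(−½(r/σ_ref)²) + B`, with `σ_ref = 0.6 Å`,
`A = avgD + 10σ`, `B = avgD − σ`. Samples closer to any other model atom
than to the query point are rejected (placed solvent counts as "other
atoms"); fewer than 4 surviving samples make Q undefined (NaN). Because
A and B are affine in the map statistics and Pearson correlation is
affine-invariant, Q is independent of the contour level to machine
precision — the tests assert this at 1e−9. Per-residue Q is the
unweighted mean over heavy atoms; per-part means use the atom-name
lookup (base ring + exocyclic; sugar C1′–C5′, O4′, O2′; OP1/OP2/O5′/O3′
as phosphate oxygens; P). Solvent B-factors are `B = 150(1 − Q)`.

The A/B amplitude convention is the reference tool's documented default
as reconstructed here; with no offline reference executable available,
its validation is the synthetic self-consistency suite (exact-Gaussian
profile → Q = 1; monotone degradation under added noise; affine
invariance).

## SWIM placement rules

Gates run in a fixed order and the first failure is the recorded
rejection reason: (1) Q at `Pmax` > 0.7 in the full map, then in both
half maps; (2) nearest RNA nucleotide's Q ≥ 0.6; (3) density ≥ `avgD +
5σ`; (4) chemistry. Chemistry classifies the peak as Mg²⁺ when an
electronegative atom (any O, or a nitrogen with no proton at neutral pH)
lies at 1.8–2.5 Å, no protonated nitrogen lies at 1.8–3.4 Å, and no
carbon within 3.0 Å; otherwise as water when an N/O lies at 2.5–3.4 Å or
a Mg²⁺ at 1.8–2.5 Å, and no C/P lies within 3.2 Å. The protonation table
(N6 of A; N1, N2 of G; N4 of C; N3 of U protonated; ring nitrogens N1/N3/
N7 acceptors) is config-overridable.

One rule here is the package's own: the lower bound of each species'
binding range also acts as a **clash floor** (water vetoed by any N/O
closer than 2.5 Å or Mg²⁺ closer than 1.8 Å; ion vetoed by any atom
closer than 1.8 Å). Without it, a density peak sitting on an existing
polar atom — every RNA atom is a watershed peak of its own — could
satisfy the ion rule and deposit Mg²⁺ on top of a phosphate oxygen. The
floor is the physical reading of "binding range": anything closer than a
hydrogen bond (or inner-sphere coordination) is an overlap, not a
partner.

Accepted solvent joins the model immediately, so later peaks see it in
distance and Q-score computations; duplicates are additionally suppressed
by `minWaterD = 2.5 Å` and `minIonD = 4.5 Å` against previously accepted
solvent of the same species. Iteration stops when a pass adds nothing
(at most 3 passes). Segmentation statistics come from the unchanged full
map; only the exclusion model is updated between passes.

## Consensus and transplantation

Candidate pairs (within 3 Å) are assigned greedily one-to-one by
ascending displacement after rigid least-squares alignment of the local
RNA context — all heavy atoms of nucleotides containing an atom within
10 Å of either solvent, matched by (chain, residue, atom name).
Consensus requires displacement ≤ 1 Å **and** mutual binding-site
containment: each member's close binders (water 2.5–3.2 Å, expanded once
by 0.3 Å if empty; Mg²⁺ 1.8–2.2 Å) must all appear within the other
member's expanded range (water 2.5–3.5 Å; Mg²⁺ 1.8–2.5 Å). The
expansion applies only to the member whose close set was empty.
Remaining categories: same-binding-site-only, superimposable-only,
partial-binder-overlap, no-overlap. Because the alignment is least
squares on the same paired atom set in either direction and the
binding-site test is mutual, consensus counts are symmetric in the two
models.

Transplantation carries each solvent of model A into map B's frame by
the same local alignment and re-evaluates the map gates (density ≥ 5σ,
full-map Q > 0.7, both half-map Q > 0.7) at the transplanted point.

Binding motifs collect, per solvent, the RNA atom names within the
species range (water 2.5–3.5 Å, Mg²⁺ 1.8–2.5 Å) with OP1/OP2 merged to
one `OP` class, aggregated by motif and by atom type.

## Density comparison

Shell vectors are z-scored by whole-map statistics. CC is Pearson over
shell voxels; MI comes from a 20×20 joint histogram with equal-width
bins over each vector's observed range (empty cells contribute zero) and
is reported in both nats and bits, since the cited convention does not
fix the base. Classification treats reference voxels above 3σ as
positives and sweeps the candidate threshold over all unique values plus
±∞ — exact curves, no binning. AU-PRC integrates the monotone
(running-maximum) interpolated precision staircase by trapezoid over
recall; AU-ROC by trapezoid over FPR; max-MCC is the maximum Matthews
coefficient over the sweep. These choices are asserted against an
independent brute-force confusion-matrix enumeration at 1e−9.

Per-nucleotide scores restrict the shell to voxels 1.8–3.5 Å from that
nucleotide's heavy atoms (and ≥ 1.8 Å from all RNA), then min-max
normalize the candidate's AU-PRC between a shuffled-control floor (0)
and an independent-map ceiling (1), clipped to [0, 1]; nucleotides whose
ceiling AU-PRC is undefined or below 0.2 are scored 0 (high experimental
uncertainty). The shuffled control permutes shell values in place with a
caller-supplied seed, leaving all other voxels untouched.

## Ensemble analysis

Frame sets are engine-agnostic: a list of per-frame RNA/water/ion
coordinate arrays, adapted from multi-model input or a
(frame, species, x, y, z) table. Frames whose RNA exceeds 3.4 Å RMSD
(after rigid superposition) to every reference structure are excluded
from site statistics. Species densities are time-averaged counts per Å³
on a 0.5 Å grid, Gaussian-smoothed by 0.4 Å (mean-preserving) so
single-frame counts do not masquerade as peaks; the default peak
threshold is twice the number density of bulk water (2 × 0.033 Å⁻³).
Watershed peaks closer than 1 Å are merged keeping the denser one.

A site's bound-atom label is the modal bound-RNA-atom set among solvent
found within 2 Å of its peak, rather than the geometric set at the peak
coordinate — the latter is fragile when an RNA atom sits near a cutoff
boundary. Frame assignment aligns each frame to every nucleotide
neighborhood (nucleotides within 10 Å), resolves multi-neighborhood
membership by proximity to the neighborhood center, and assigns a
solvent to a site when it is within 2 Å of the peak and binds the
identical atom set (ions 1.8–2.5 Å, waters 2.5–3.5 Å). Occupancy is
bound-frames over retained frames; water RMSF is over aligned member
coordinates; Mg²⁺ residence events merge across single-frame gaps.
Composite densities average submaps whose centers lie within 10 Å of a
voxel, weighted by inverse distance to the submap center; uncovered
voxels are NaN. RNA flexibility aligns frames to the ensemble mean (two
passes), averages atom RMSF per residue without mass weighting, and
converts via `B = (8π²/3)·RMSF²`. Molarity converts to number density as
`M·N_A/10²⁷` (55 M ↔ 0.033 Å⁻³).

## Synthetic data: what it emulates, what it does not

`make_rna` builds an idealized A-form duplex from internal coordinates:
planar idealized base rings, a C3′-endo-like ribose closed to ~1.54 Å,
A-form backbone torsions, rise 2.81 Å and twist 32.7° per step. The
rigid pose of the nucleotide in the helix frame and the complementary
strand's dyad transform were optimized once so successive residues
connect through their phosphates (O3′–P ≈ 1.7 Å) without steric
clashes; the constants are frozen in the source. The geometry is
fiber-model quality: atom names, protonation classes, part lookups and
all distance rules behave as on a real structure, but the model is not
refinement-grade (no sequence-dependent geometry, no base-pair
hydrogen-bond optimization).

`make_maps` simulates Gaussian-atom signal for the RNA plus planted
solvent and adds **band-limited** Gaussian noise independently to each
half map (white noise smoothed to the map resolution and rescaled);
the full map is the mean of the halves. Real reconstruction noise is
band-limited, and white voxel noise would make the interpolated field
jagged at sub-voxel scale in a way no experimental map is. Default
conditions: 2.2 Å resolution, 0.5 Å voxels, SNR 10 (planted water peak
amplitude over half-map noise sd), full occupancy, five waters anchored
2.9 Å from O acceptors and one Mg²⁺ at 2.1 Å from a phosphate oxygen.
Planted positions are searched so the species' placement geometry holds
everywhere within 0.3 Å of the site, so noise-scale peak shifts cannot
flip the classification — under these conditions waters peak near 8σ and
the Mg²⁺ (1.5× amplitude) near 12–14σ, bracketing the 5σ gate from
above, while noise features fail it. What passing tests show is that the
pipeline recovers ordered solvent under controlled SNR and geometry;
they do not probe partial occupancy, radiation damage, B-factor
heterogeneity, or misassigned monovalent ions.

`make_ensemble` plants binding sites with per-site occupancy and
positional jitter, diffuse waters uniform in the 2.5–3.5 Å shell (the
storage convention cuts waters beyond 3.5 Å from RNA, so distal solvent
is absent by design), and optionally a fraction of frames with one
strand displaced so the RMSD retention filter has true positives to
reject. Bound-site jitter is rejection-sampled to preserve the site's
bound-atom set — a physically bound water rattles within its site
without exchanging partners; free Gaussian jitter would flicker the
binder set at range boundaries and make exact-set assignment
meaninglessly strict.

## Problem sizes and defaults

The default fixture is a 6-bp duplex on a ~66×70×92 grid; the strictness
assessment uses a 56-bp duplex to provide >10⁴ solvent-shell lattice
points at the 1.67 Å spacing; ensemble recovery uses 500 frames (3 sites
at occupancies 0.2/0.5/0.9) and RMSF recovery 1000 frames. These sizes
give binomial standard errors comfortably inside the asserted tolerances
(±0.05 occupancy; 5% RMSF) while keeping the whole suite and the
acceptance script fast on a single CPU.

## Known limitations

- Approximate nucleotide geometry (see above); chain B is generated by a
  dyad that yields a duplex-like arrangement, not a base-paired helix.
- Q-score A/B amplitude constants are a reconstruction of the reference
  tool's default; absolute Q values on real maps may differ slightly,
  though all thresholds in the pipeline act on the same convention.
- Watershed on heavily plateaued grids splits exact-equal-value plateaus
  deterministically by voxel index, which may differ from other tools.
- No partial-occupancy or alternate-conformer solvent, no Na⁺/Cl⁻
  assignment, no second-shell (water-mediated) Mg²⁺ sites.
- Mutual information on modest shells is biased upward by histogram
  sparsity, as for any plug-in MI estimator.
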