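# Methods

## The morphing model

`mapmorph` assumes the starting model is *locally* correct — residues and
their immediate neighbourhoods have nearly the right internal structure — but
displaced from the true structure by a deformation that varies slowly along
the chain. Under that assumption the deformation is well approximated by one
translation per residue, constrained to vary smoothly with residue number.
Each cycle estimates those translations from the density, smooths them, and
applies them rigidly per residue; harmonic regularization then repairs the
inter-residue geometry the independent translations distorted. Rotations are
deliberately not searched: over the ±2 Å scale of one residue's displacement
a rotation is second-order, and the smoothing of neighbouring translations
reproduces slowly varying rotational motion (a hinge) as a linear gradient of
translations.

All maps live on periodic grids over a P1 cell; models in other space groups
must be expanded to P1 first. Coordinates are orthogonal ångströms
everywhere; fractionalization happens only inside the density module.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `r_morph` | 6.0 | Å | radius of the local density sphere searched per residue; suited to ~3 Å maps, and uncritical because smoothing spans a much larger region |
| `r_max` | 2.0 | Å | largest translation considered; also the bound honoured by the synthetic deformation fields |
| `cc_min` | 0.05 | – | local-correlation threshold below which a residue's raw shift is excluded from smoothing |
| `window` | 11 | residues | smoothing window; regression (not a weighted mean) because points may be excluded |
| `n_cycles` | 6 | – | shifts decay rapidly after the first cycle; iteration also stops early once the mean applied shift < 0.05 Å |
| `d_min` | 3.0 | Å | nominal map resolution; sets the atom blur and the grid |
| `grid_factor` | 1/4 | – | grid spacing as a fraction of `d_min` (kept within [d_min/4, d_min/3]) |
| `smooth_on` | `dx_cent` | – | which search vector feeds smoothing (see below) |

Regularizer weights: `w_bond` 1.0 Å⁻², `w_angle` 0.1 deg⁻², `w_pos` 0.05 Å⁻²
(anchoring atoms to their cycle-start positions), `w_map` 0.2 (density pull,
normalized by the map r.m.s.), step tolerance 1e-4 Å, 200 steps of steepest
descent with backtracking. Ideal bond lengths and angles are standard
Engh–Huber-type backbone values.

## Density model

Model maps are sums of periodic isotropic Gaussians, one per atom, with
σ² = B/(8π²) + (0.356·d_min)² and integral equal to atomic number ×
occupancy. The second term approximates the blur introduced by Fourier
truncation at the map resolution. This is a real-space stand-in for a
structure-factor F_calc synthesis: the properties morphing relies on — peak
positions, smooth atom-centred overlap — do not depend on the exact radial
profile. Gaussians are truncated at 4.5σ (relative error ~4 × 10⁻⁵ of the
peak).

## Numerical choices

* **Overlap sign convention.** O(**x**) is the overlap of the *model
  displaced by +**x*** with the target, computed as a cross-correlation via
  `rfftn`/`irfftn` over the full cell. The returned shift is therefore the
  vector *added* to the residue's coordinates; the convention is pinned by
  oracle tests against brute-force summation and against cyclically shifted
  targets.
* **Peak centroid (Δx_cent).** The face-connected region (periodic, 6-face
  connectivity) around the in-ball argmax with
  O ≥ O_bg + 0.9·(O_max − O_bg), where O_bg is the in-ball minimum, each
  point weighted by its height above that threshold. Referencing the local
  background matters: at 3 Å resolution the overlap peak is broad and rides
  on a positive pedestal filling most of the 2 Å search ball, and a centroid
  weighted by raw O collapses toward the ball centre (observed median
  recovery error ~1 Å on a 1.2 Å rigid displacement, vs ~0.15–0.2 Å with the
  background-referenced weighting). The high threshold also suppresses the
  small systematic pull that density from adjacent residues exerts on the
  centroid, which otherwise shows up as spurious ~0.2 Å shifts even when the
  model already matches the map.
* **Ties and degenerate cases.** Argmax ties break to the smallest offset
  length, then lexicographic index order. If no positive overlap exists in
  the ball, both vectors are zero and the residue is flagged and excluded.
  A flat (constant) overlap returns the argmax with no sub-grid refinement.
  Zero variance on either side of a correlation yields cc = 0 and exclusion,
  not an error, inside the search; the standalone whole-map correlation
  raises on constant maps.
* **dx_cent vs dx_max.** The argmax vector is quantized to the grid
  (~0.75 Å at the defaults), the centroid is sub-grid; the centroid is the
  initial offset estimate and is what smoothing consumes by default, with
  `smooth_on="dx_max"` available as a switch. Recovery on known rigid
  displacements is ~4× more accurate with the centroid.
* **Local correlation sphere.** cc_local compares the local model map inside
  its r_morph sphere against the target sampled at the Δx_max-*shifted*
  positions (whole grid steps, so values stay on-grid).
* **Window truncation.** At segment ends the regression is fitted to the
  available in-segment points and evaluated at the residue (extrapolating at
  termini). Windows with fewer than two included residues fall back to the
  residue's own shift (if included) or zero, with a flag.
* **Regularizer descent.** Steepest descent normalized so the largest
  per-component move equals the current step size, with backtracking halving
  and 1.5× growth on acceptance; energy is non-increasing by construction.
  The map force is evaluated by central differences (h = 0.05 Å) of the
  trilinear interpolant.

## Synthetic ground truth

The generator builds ideal poly-alanine models from internal coordinates
(Engh–Huber bonds/angles, α-helix torsions −57°/−47°, ω = 180°), so the
regularizer's restraints are satisfied exactly by construction. Scenarios:

* **rigid** — 20-residue helix displaced by a random 1.2 Å translation;
* **hinge** — two 12-residue helices joined by a 3-residue extended linker,
  the arms counter-rotated about an axis displaced 30 Å from the molecule.
  The displaced axis makes the per-residue displacement nearly uniform along
  each arm; the angle is set so the largest CA displacement is 1.9 Å, just
  inside the search radius, which puts the start-vs-truth main-chain
  r.m.s.d. in the 1.0–2.0 Å band typical of distant molecular-replacement
  templates;
* **sinusoid** — 1 Å-amplitude displacement wave (wavelength 10 residues)
  along a helix;
* **null** — start model identical to the truth.

Target maps are calculated from the truth at d_min 3.0 Å (the regime in
which the 6 Å `r_morph` default is appropriate). Deformations are applied as
one translation per residue — the displacement of the residue's CA under the
field — mirroring exactly the class of motions the search can represent, and
the field is stored with the case so recovery can be scored against the
exact inverse. All randomness flows through a seeded generator; a case is
bitwise reproducible from its seed.

What the fixtures do **not** emulate: experimental noise, solvent and bulk
density, model bias in the target map (2mFo−DFc, density-modified and OMIT
maps are consumed as inputs, never computed), crystallographic symmetry
beyond P1, sequence differences between template and target, and per-atom
(as opposed to per-residue) deformations. Passing results therefore
demonstrate the mechanics of the search/smooth/apply/regularize loop and its
convergence on recoverable deformations — not performance against noisy,
biased experimental maps.

## Design decisions taken where the design was open

* Which vector feeds smoothing (centroid vs argmax) is genuinely ambiguous;
  both are computed and exposed, the centroid is the default (it is the
  stated initial offset estimate and is empirically the more accurate).
* The reciprocal-space refinement stage of a production pipeline is replaced
  by the real-space regularizer above; its purpose here is only to restore
  chemically reasonable geometry after per-residue translation, optionally
  biased toward the map.
* Alternate locations keep the highest-occupancy conformer (first on ties);
  insertion codes break consecutive numbering and hence smoothing windows;
  waters and ligands are read but excluded from the search set and from
  main-chain metrics.
* Percentile interpolation for the spread is linear between order statistics
  (zero-based rank p/100 × (n−1)); nearest-atom metric distances are plain
  Euclidean in the given frame, with no minimum-image wrapping and no
  identity or residue-correspondence constraint (the comparison is
  asymmetric in its arguments by design).

## Known limitations

* Translations only; a residue rotated in place is corrected only via the
  smoothed translations of its neighbours plus regularization.
* Deformations larger than `r_max` per residue are invisible to the search.
* Under forced long iteration with the density bias enabled, the regularizer
  re-anchors its positional restraint each cycle and can slowly compress the
  model toward overlapping neighbour density (~0.05 Å/cycle on a 3 Å map
  until bonded terms resist); the default early stop halts iteration well
  before this matters, and `w_map=0` removes it entirely.
* Overlaps between a displaced residue and density belonging to other
  residues are ignored during the search, as is density "stolen" from
  adjacent residues; smoothing absorbs most such artefacts.
* The problem sizes used throughout (20–27-residue fixtures, ~40 Å cells,
  3 Å maps) are desk-scale choices that keep every example reproducible in
  seconds while exercising every code path; nothing in the implementation
  is specific to them.
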