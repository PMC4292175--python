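# tomopack

Particle-packing analysis and membrane morphometrics for cryo-electron
tomography volumes.

`tomopack` answers a concrete structural question: are densely packed,
quasi-spherical macromolecular complexes in a tomogram — the motivating
case is RuBisCO inside the *Chlamydomonas reinhardtii* pyrenoid —
arranged on a close-packed lattice, and at what centre-to-centre
spacing? It also implements the accompanying membrane measurements:
line-scan densitometry of thylakoid stacks and counting statistics for
chloroplast-envelope invaginations.

## The method

The pipeline has four stages, each usable on its own:

1. **Template matching** (`volmatch`). Particles are localized with a
   spherical template (default diameter 13.68 nm), which makes the
   orientation search unnecessary. The volume is first low-pass
   filtered to the resolution the tilt sampling supports for a particle
   of diameter *D* (Crowther criterion, *d* = π·*D*/*N* with
   *N* = 180°/increment, clamped at Nyquist), then a locally normalized
   cross-correlation map is computed under a spherical mask and peaks
   are exhaustively extracted under a hard-sphere exclusion radius.
2. **Subtomogram averaging** (`subtomo`). Cubic subvolumes (default
   edge 45.6 nm) around the detected positions are iteratively aligned
   to their evolving average on a coarse-to-fine ZYZ Euler grid with an
   FFT shift search, without imposing any symmetry. Resolution is
   estimated by Fourier shell correlation at the 0.5 threshold.
3. **Neighbor clouds** (`neighborhood`). A 22.8 nm range query collects
   each particle's neighbor offsets; the per-particle alignment
   rotations map every neighborhood into the average's common frame and
   the pooled 3D point cloud is clustered with k-means (k = 13: the
   reference particle plus its 12 contact neighbors).
4. **Hard-sphere lattice fitting** (`latticefit`). Ideal HCP, CCP and
   BCC neighborhoods are generated over a scan of sphere diameters
   (default 10–20 nm in 0.05 nm steps with a 0.01 nm refinement pass),
   rotationally registered to the cluster centers (coarse rotation grid
   plus iterative closest-correspondence with an SVD rotation solve),
   and scored by nearest-correspondence RMSD. The model and diameter
   with the global minimum win: for hexagonal close packing,
   coordination 12 with A-B-A layering.

A synthetic-data generator (`latticegen`) produces ground-truthed
jittered lattices rendered as soft spheres with Gaussian noise and an
optional missing wedge, layered membrane-stack phantoms, and annotated
invagination fixtures, so every stage can be tested for parameter
recovery. The morphometric module (`morpho`) measures stack repeats by
autocorrelation, layer widths by half-maximum crossings, and applies
the invagination counting rule *i* > *m* (stromal projection larger
than the envelope double-membrane width).

## Worked example

Fit the packing model of a synthetic pyrenoid-like scene end to end:

```sh
tomopack simulate lattice --model hcp --diameter 15.05 --jitter 0.75 \
    --extent 110,110,110 --voxel-size 1.14 --noise 1.0 --seed 11 \
    --out scene.csv --volume-out scene.mrc
tomopack match --volume scene.mrc --min-score 0.3 --out particles.csv
tomopack average --volume scene.mrc --particles particles.csv \
    --angular-schedule 45,45 --max-shift 3 --bin 2 \
    --out avg.mrc --transforms-out transforms.csv
tomopack cloud --particles particles.csv --transforms transforms.csv \
    --contact-filter --out centers.csv
tomopack fit --centers centers.csv --out fit.json
```

which prints

```
575 particles -> scene.csv
rendered volume -> scene.mrc
360 particles -> particles.csv
average of 113 boxes -> avg.mrc (final mean score 0.545)
transforms -> transforms.csv
1463 cloud points, 13 centers -> centers.csv
best model hcp at 14.98 nm (RMSD 0.307 nm)
```

The disordered-looking scene is correctly identified as hexagonal
close packing of ~15 nm hard spheres (the generating truth was
15.05 nm with 5% positional jitter at signal-to-noise 1); the cluster
centers deviate from the ideal lattice by 0.31 nm RMS. The alignment
step matters: the two HCP sublattices carry 60°-rotated coordination
environments, and only pooling under the per-particle alignment
rotations collapses the neighbor cloud onto the 12 ideal directions.
`fit.json` retains the full RMSD-versus-diameter curve for each
candidate model. With a 15 nm centre spacing, `tomopack.surface_gap`
gives the space left between particle surfaces: 4.5 nm face-to-face
for a 10.5 nm short axis, 2.0 nm corner-to-corner for a 13 nm long
axis.

Membrane morphometrics works the same way from the shell:

```sh
tomopack simulate stack --membrane 4.9 --lumen 9.0 --gap 3.6 --out stack.mrc
tomopack morpho profile --volume stack.mrc --start 0.2,12,0.5 \
    --end 132,12,0.5 --width 80 --out profile.csv
tomopack morpho layers --profile profile.csv --out layers.json
# -> repeat 22.42 nm -> layers.json
```

## Layout

```
src/tomopack/
  core.py          shared containers, MRC/CSV I/O, rigid transforms
  latticegen.py    synthetic scenes, membrane stacks, fixtures
  volmatch.py      template matching
  subtomo.py       subvolume averaging and FSC
  neighborhood.py  range queries, pooled clouds, k-means centers
  latticefit.py    registered-RMSD lattice model selection
  morpho.py        densitometry and invagination statistics
  cli.py           `tomopack` command-line surface
docs/methods.md    model assumptions, parameter choices, limitations
```
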