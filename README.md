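# confluence

Modelling of the mesiotemporal cortical confluence: a continuous surface
model joining isocortical and allocortical (hippocampal) mesh pairs, a
signed geodesic iso-to-allocortical axis, equivolumetric depth-wise
microstructure profiling, cytoarchitectural gradient extraction,
supervised axis prediction, axis-binned directed-connectivity analysis,
and correspondence of the axes with macroscale functional gradients under
spin-permutation inference.

Every stage is exercisable offline on synthetic data with analytic ground
truth: the `confluence.synthetic` module generates confluent toy meshes
(an isocortical ramp meeting a spiral-curled allocortical sheet at a
bridgehead seam), intensity volumes with programmed depth-profile
skewness, stable linear stochastic dynamics with known directed coupling,
and spherical parcel timeseries with programmed low-rank gradients.

## Layout

| module                   | role |
|--------------------------|------|
| `confluence.synthetic`   | seed-deterministic fixtures with ground truth |
| `confluence.mesh`        | triangle meshes with per-vertex scalar fields |
| `confluence.surfaces`    | bridgehead detection, stitching, geodesic axis |
| `confluence.depths`      | equivolumetric depth surfaces, profile sampling, central moments |
| `confluence.cytoarch`    | microstructure profile covariance, diffusion map embedding, polynomial selection, per-slice fits |
| `confluence.predict`     | random-forest axis regression with importance-based feature selection |
| `confluence.dynamics`    | axis bin atlases, OU-inversion effective connectivity, edge deviation analyses |
| `confluence.macroscale`  | axis r-maps, functional gradients, spin tests, SNR controls |
| `confluence.stats`       | adjusted R², dependent-correlation z, partial correlation |
| `confluence.io`          | GIFTI / NIfTI / PLY / TSV readers and writers |

## CLI

```sh
confluence synth --out data/ --seed 0            # synthetic dataset + ground truth
confluence stitch --iso-pial data/iso_pial.surf.gii \
    --iso-white data/iso_white.surf.gii \
    --allo-inner data/allo_inner.surf.gii \
    --allo-outer data/allo_outer.surf.gii \
    --pd-field data/allo_pd.func.gii --out model/
confluence axis --model model/
confluence profile --model model/ --volume data/intensity.nii.gz --out profiles.tsv
confluence gradient --profiles profiles.tsv --out gradients.tsv
confluence predict-axis --profiles profiles.tsv --repeats 100 --seed 0 --out report.tsv
```

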