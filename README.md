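# granulekit

Quantitative analysis of phase-separated germ granules from fluorescence
microscopy: granule morphometry and fold enrichment, FRAP / FLIP /
photoconversion kinetics, 3-D counting of germ-plasm-associated nuclei, and
DNA-content cell-cycle deconvolution — plus synthetic-data generators that
emulate every one of those inputs with known ground truth, so each estimator
can be validated by parameter recovery.

## Who this is for

Labs studying biomolecular condensates (germ granules, P granules, nuclear
bodies) who quantify granule images and photobleaching experiments and want
those measurements as tested, scriptable functions rather than ad-hoc
ImageJ + spreadsheet workflows. The package distinguishes liquid-like
condensates — where nearly all protein exchanges rapidly — from
phase-transitioned, hydrogel-like granules in which a large fraction is
immobile.

## The core model

A bleached region recovers as

```
f(t) = a · (1 − exp(−b t)),        t½ = ln 2 / b
```

where **a** is the *mobile fraction* (the plateau of the normalized recovery
curve: the proportion of fluorophore exchanging with the surroundings) and
**b** the recovery rate constant. Traces are background-subtracted,
reference-normalized and rescaled *full-scale* so that the pre-bleach mean is
exactly 1 and the first post-bleach value exactly 0; curves are averaged
across ROIs before the nonlinear fit. FLIP sessions are expressed as percent
fluorescence remaining per region, with depletion corrected by a control
bleach target outside the specimen. Multi-granule exchange (FLIP,
photoconversion) is modeled as a linear compartment system

```
dF_i/dt = Σ_j k_ij (F_j,mobile − F_i,mobile) − [i = bleached] k_bleach F_i − k_img F_i
```

with the immobile fraction excluded from exchange. Morphometry converts
granule areas to diameters with the field convention d = 2·√A (the circular
convention d = 2·√(A/π) is available and labeled), and fold enrichment is the
ratio of mean per-area granule intensity to a reference compartment
(intergranular space, cytoplasm or nucleoplasm).

## Worked example

```
$ python examples/frap_fitting.py
mobile fraction a = 43.9 % (fit SE 0.07)
rate b            = 0.0647 /s
half-time t1/2    = 10.7 s   (ln 2 / b)
r^2               = 0.9842 over 10 curves
```

Ten simulated traces with a true 43.6% mobile fraction and 10.5 s half-time
(2% Gaussian noise) are normalized, averaged and fitted; the pipeline
recovers the truth within a fraction of a point. The other scripts in
`examples/` walk through segmentation + enrichment, FLIP redistribution,
photoconversion exchange, 3-D nucleus counting, cell-cycle deconvolution,
and the config-driven pipeline runner.

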