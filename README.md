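# flexbeam

Aligned Peak Response (APR) beamforming for flexible ultrasound array
transducers.

## The problem

A flexible array transducer conforms to the patient's body surface, which
makes it attractive for ultrasound-guided radiotherapy: it can stay strapped
to the abdomen and track tumor motion during treatment without a robotic
arm pressing a rigid probe into the skin. The price of flexibility is that
the bent array's element positions are unknown — they change with the body
surface and with breathing — so a conventional delay-and-sum (DAS)
beamformer, which computes each channel's time of flight (ToF) from the
known element coordinates, applies the wrong delays and the B-mode image
falls apart.

APR sidesteps shape estimation entirely. An *assistant structure* — a gel
standoff with embedded hyperechoic markers — is placed on the skin under
the probe. Every element receives a strong peak echo from a marker, and the
delays needed to focus the image are estimated by *aligning those peaks*
across the data, in two rounds:

1. **Round 1 (transmit/reference delays).** Each scanline fires a single
   element and receives on all 128. The trace received by the scanline's
   own transmitting element is its reference; the integer sample shift
   `d = Δt · fs` that aligns its gated peak to the reference scanline's
   peak becomes the per-scanline delay.
2. **Round 2 (receive delays).** After round 1 is applied, the remaining
   128 receive traces within each scanline are aligned to the transmitting
   element's trace the same way. Element-to-element delay jumps larger
   than a threshold (5 samples) are clamped while walking outward from the
   transmit element — an outlier guard against weak or inconsistent echoes.

The total delay per (scanline, element) column is `round1 + round2`;
applying it, summing across the element dimension, envelope detection and
log compression produce the B-mode image. The delays are fixed-focus
(constant along depth), which is the method's documented resolution
limitation away from the marker depth.

The package contains everything needed to exercise this without hardware:

| module | what it does |
|---|---|
| `flexbeam.geometry` | flat / circular-arc / polyline apertures, exact two-way ToF |
| `flexbeam.simulate` | desk-scale RF channel-data simulator (ToF-exact pulse replicas, 1/(r·r) spreading) and `curve_rf`, the artificial-curvature transform |
| `flexbeam.preprocess` | global and depth-gated normalization, trace and delay-curve (Savitzky–Golay) smoothing |
| `flexbeam.apr` | two-round APR estimation, delay application, geometric oracle delays |
| `flexbeam.beamform` | APR fixed-focus summation and dynamic-receive-focus DAS reference, envelope detection, log compression |
| `flexbeam.metrics` | FWHM, CNR, PSNR, location error, delay-curve error |
| `flexbeam.io` / `flexbeam.pipeline` / `flexbeam.cli` | HDF5 / raw+JSON containers, YAML run configs, end-to-end pipeline with manifest, `flexbeam` CLI |

## Worked example

Simulate the single point target at lateral 0 mm, axial 30 mm on a flat
128-element, 1 mm-pitch probe (c = 1540 m/s, fs = 40 MHz, one transmit
element per scanline), estimate delays with two-round APR — *without using
the geometry* — and beamform:

```python
from flexbeam import (APRConfig, Pulse, beamform_apr, estimate_delays,
                      make_geometry, make_marker_phantom, simulate_rf)

geometry = make_geometry("flat", n_elements=128, pitch=1.0)
rf = simulate_rf(make_marker_phantom("center_point"), geometry, Pulse())
delays = estimate_delays(rf, APRConfig())
image = beamform_apr(rf, delays)
z, x = image.argmax_location()
print(f"brightest pixel at z={z:.2f} mm, x={x:.2f} mm")
```

prints

```
brightest pixel at z=30.01 mm, x=-0.50 mm
```

i.e. the target is recovered at its true depth to 0.01 mm and at the
nearest scanline column (element centers sit at ±0.5 mm for the even
128-element aperture). The same run from the shell:

```bash
flexbeam run --phantom center_point --shape flat --out-dir out/
```

writes the APR image, the DAS ground-truth image, the delay-curve CSV, a
metrics row (FWHM/CNR/PSNR/location error/delay errors) and a hashed
manifest. `flexbeam simulate | curve | apr | beamform | evaluate` expose
the individual stages; `--help` on any verb lists its options.

To mimic a bent probe with known ground truth, flat-acquisition RF data
can be artificially curved and then reconstructed with the curved-geometry
DAS:

```bash
flexbeam simulate --phantom center_point --out rf.h5
flexbeam curve --rf rf.h5 --radius 500 --out rf_curved.h5
flexbeam beamform --rf rf_curved.h5 --out curved.png
```

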