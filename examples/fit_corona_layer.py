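"""Stepwise two-wavelength layer fitting of a vesicle film plus corona.

Renders noise-free spectra for the capture stage (100 nm film, n 1.3345)
and the corona stage (5.5 nm slab, n 1.365 on top), then solves the two
layers sequentially: the capture layer is fitted first and frozen before
the corona is fitted, so the corona estimate uses the capture signal as
its baseline. Thickness is shared between wavelengths; the refractive
index is fitted independently per wavelength.
"""

import sprcorona as sp
from sprcorona.layerfit import CORONA_LAYER_BOX, EV_LAYER_BOX
from sprcorona.optics import OpticalLayer, reflectance_tmm

WLS = (670.0, 785.0)
grid = sp.InstrumentModel(angle_step=0.05).angle_grid()


def film(name, d, n):
    return OpticalLayer(name, d, {wl: complex(n) for wl in WLS})


def render(stack):
    return {
        wl: sp.AngularSpectrum(wl, grid, reflectance_tmm(stack, wl, grid))
        for wl in WLS
    }


base = sp.kretschmann_stack()
capture_truth = base.insert_layer(2, film("ev", 100.0, 1.3345))
corona_truth = capture_truth.insert_layer(3, film("corona", 5.5, 1.365))

results = sp.fit_stack_sequential(
    [("capture", render(capture_truth)), ("corona", render(corona_truth))],
    base,
    [
        sp.LayerFitSpec(name="capture", **EV_LAYER_BOX),
        sp.LayerFitSpec(name="corona", **CORONA_LAYER_BOX),
    ],
)

print("stage      d (nm)    n(670)    n(785)    residual")
for res in results:
    print(
        f"{res.name:<9} {res.d:8.3f}  {res.n[670.0]:.5f}  {res.n[785.0]:.5f}  "
        f"{res.rss_total:.2e}"
    )
print("truth:     capture 100.000 / n 1.3345, corona 5.500 / n 1.3650")
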