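"""Interpret MS/MS spectra of alendronic acid as neutral-loss chains.

The protonated drug (m/z 250.024) fragments by losing phosphonic acid
(H3PO3), then water, then metaphosphorous acid (HPO2); the deprotonated
drug loses H3PO3 and water in one observed step. Each product peak is
annotated with the loss chain whose theoretical m/z matches and whose
intermediate fragments are themselves observed.
"""

import hostguest as hg
from hostguest import reference as ref

registry = [ref.HOST, ref.GUEST]

for label, polarity, rows in (
    ("[AlnH + H]+", "positive", ref.MSMS_POSITIVE_ALN),
    ("[AlnH - H]-", "negative", ref.MSMS_NEGATIVE_ALN),
):
    precursor = hg.parse_ion_label(label, registry)
    spectrum = hg.Spectrum(
        polarity, tuple(hg.Peak(mz, 10.0) for mz, _ in rows), precursor=precursor
    )
    print(f"\nprecursor {label}  m/z {hg.mz_of_ion(precursor):.4f}")
    for ann in hg.interpret_msms(precursor, spectrum):
        print(f"  obs {ann.peak.mz:9.3f}  theo {ann.chain.mz:9.4f}  "
              f"{ann.delta_m*1e3:+6.2f} mDa   {ann.chain.describe()}")
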