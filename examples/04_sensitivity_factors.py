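"""Monte Carlo sensitivity factors of <t> to layer absorption changes.

The head model is 10 layers of 0.2 cm probed at a 3 cm source-detector
distance.  SF_k = -d<t>/dmua_k (ps cm) peaks at intermediate depth (the
photon "banana") and the intracerebral factor is the sum over layers 5-10
(0.8-2.0 cm).  The factors convert measured d<t> into absorption changes:
dmua = -d<t> / SF.
"""

from trfnirs import OpticalLayerStack, intracerebral_sf, run_sensitivity_mc

stack = OpticalLayerStack()  # mua 0.17 /cm, musp' 10 /cm, n 1.4 per layer
profile = run_sensitivity_mc(stack, mc_photons=300_000, seed=1)

for wl in (760.0, 830.0):
    sf = profile.sf_ps_cm[wl]
    se = profile.se_ps_cm[wl]
    print(f"-- {wl:.0f} nm --")
    for k, (s, e) in enumerate(zip(sf, se), start=1):
        depth = (k - 1) * 0.2
        print(f"  layer {k:2d} ({depth:.1f}-{depth + 0.2:.1f} cm): "
              f"SF = {s:7.1f} +/- {e:4.1f} ps cm")
ic = intracerebral_sf(profile)
print(f"intracerebral SF (sum of layers 5-10): "
      f"{ic[760.0]:.0f} ps cm @ 760 nm, {ic[830.0]:.0f} ps cm @ 830 nm")
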