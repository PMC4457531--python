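"""How the smoothing width changes the signal-to-noise ratio of one pixel.

SNR first rises with the filter width as pixel noise is averaged away, then
falls once the kernel grows past the response's spatial footprint and
smears it into unresponsive tissue.  The curve guides the choice of sigma.
"""

from dffpipe import SurrogateConfig, generate_recording, snr_vs_filter_width
from dffpipe.experiments import DEFAULT_WINDOW

cfg = SurrogateConfig(width=160, height=120, magnitude=0.05, noise_level=0.1, seed=3)
seq, _ = generate_recording(cfg)

print("sigma(px)    SNR")
for sigma, snr in snr_vs_filter_width(seq, [0, 1, 2, 4, 8, 16, 32, 64], DEFAULT_WINDOW):
    print(f"{sigma:>8.0f} {snr:>7.2f}")
print("SNR = peak dF/F in the response window / residual std on baseline frames")
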