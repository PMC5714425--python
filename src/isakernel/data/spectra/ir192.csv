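# Ir-192 reduced gamma line set (NuDat-style principal lines; energies keV, intensities per decay)
energy_keV,intensity
205.79,0.0334
295.96,0.287
308.46,0.2968
316.51,0.8285
468.07,0.4781
484.58,0.0319
588.58,0.0452
604.41,0.0820
612.46,0.0534
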