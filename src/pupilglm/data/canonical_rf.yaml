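# Canonical gamma response-function parameter sets for fear-conditioned
# pupil size responses (CS+US- minus CS- difference waves), plus the
# response to the US itself.  theta is the gamma scale parameter in
# seconds; c is the time integral of the response (z-units x s); t0 is the
# onset latency in seconds.  The 'us' set's t0 is referenced to CS onset
# under a 3.5-s CS/US interval.  Registry is read-only.
exp1:      {k: 7.18,  theta: 0.52, c: 1.7, t0: 0.002}   # auditory CS (development)
exp2:      {k: 1.96,  theta: 3.40, c: 3.2, t0: 1.351}   # auditory CS
exp3:      {k: 1.85,  theta: 2.71, c: 3.4, t0: 1.288}   # visual CS
exp4:      {k: 22.52, theta: 0.21, c: 0.5, t0: 0.001}   # somatosensory CS
combined:  {k: 5.94,  theta: 0.75, c: 1.7, t0: 0.002}   # four experiments pooled
us:        {k: 1.90,  theta: 1.57, c: 2.9, t0: 3.76}    # US response (CS-referenced)
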