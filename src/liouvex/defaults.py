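"""Global switches, SIMPSON-style.

``Defaults`` is a plain dict consulted at run time:

* ``"cache"`` (True): recycle rotor-step propagators (gamma-COMPUTE style)
  and orientation-specific relaxation matrices.
* ``"parallel"`` (False): evaluate the powder loop of propagator
  construction with joblib workers. Usually not worth it for small systems
  since BLAS already threads.
* ``"n_field_cache"`` (10): number of distinct RF field settings for which
  separate propagator caches are kept (LRU beyond that).
"""

Defaults = {
    "cache": True,
    "parallel": False,
    "n_field_cache": 10,
}
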