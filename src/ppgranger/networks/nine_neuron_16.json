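{
 "name": "nine_neuron_16",
 "n_neurons": 9,
 "observed": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9
 ],
 "edges": [
  {
   "source": 1,
   "target": 1,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 2,
   "target": 2,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 3,
   "target": 3,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 4,
   "target": 4,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 5,
   "target": 5,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 6,
   "target": 6,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 7,
   "target": 7,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 8,
   "target": 8,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 9,
   "target": 9,
   "coefficients": [
    -0.6,
    -0.5,
    -0.4
   ]
  },
  {
   "source": 1,
   "target": 2,
   "coefficients": [
    1,
    2,
    2
   ]
  },
  {
   "source": 2,
   "target": 3,
   "coefficients": [
    1,
    2,
    2
   ]
  },
  {
   "source": 3,
   "target": 1,
   "coefficients": [
    1,
    2,
    2
   ]
  },
  {
   "source": 4,
   "target": 5,
   "coefficients": [
    1,
    2,
    2
   ]
  },
  {
   "source": 5,
   "target": 6,
   "coefficients": [
    1,
    2,
    2
   ]
  },
  {
   "source": 6,
   "target": 3,
   "coefficients": [
    0,
    0,
    0,
    -0.8,
    -0.9,
    -0.5
   ]
  },
  {
   "source": 9,
   "target": 1,
   "coefficients": [
    0,
    0,
    0,
    1,
    2,
    1
   ]
  }
 ],
 "baseline_rate_hz": 18.0,
 "delta_s": 0.001,
 "refractory_s": 0.001
}
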