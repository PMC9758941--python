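{
  "description": "Published bivariate quadratic runtime surfaces for the five hot functions of a BLASTN job on the reference node type (Type V). Coefficients are in the fixed term order [x^2, x*y, y^2, x, y, 1] with y = query sequences in millions and x = database sequences in millions, log-transformed for func_a and func_e. The log base is not stated in the published table; natural log is assumed and recorded here.",
  "node_type": "V",
  "surfaces": {
    "func_a": {
      "coefficients": [-3.0722, 143.6097, 3.7202, 22.4770, 881.6166, 30.0805],
      "x_transform": "log",
      "log_base": 2.718281828459045
    },
    "func_b": {
      "coefficients": [0.0, 92.8758, 0.0, 0.1523, 244.7267, 0.4292],
      "x_transform": "identity",
      "log_base": 2.718281828459045
    },
    "func_c": {
      "coefficients": [0.0, 4429.4587, 0.0, 57.7969, 94.9201, 0.1854],
      "x_transform": "identity",
      "log_base": 2.718281828459045
    },
    "func_d": {
      "coefficients": [0.0, 19.2608, 0.0, -2.6282, 90.1090, 0.2345],
      "x_transform": "identity",
      "log_base": 2.718281828459045
    },
    "func_e": {
      "coefficients": [-2.0973, 33.3526, 2.0294, 12.8749, 181.6523, 18.8566],
      "x_transform": "log",
      "log_base": 2.718281828459045
    }
  }
}
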