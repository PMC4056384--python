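energy_keV,yield_per_decay_per_keV
1.000000e+00,1.657527e-01
1.026227e+00,1.615124e-01
1.053141e+00,1.573805e-01
1.080761e+00,1.533541e-01
1.109106e+00,1.494307e-01
1.138194e+00,1.456075e-01
1.168045e+00,1.418821e-01
1.198678e+00,1.382518e-01
1.230116e+00,1.347144e-01
1.262377e+00,1.312673e-01
1.295485e+00,1.279083e-01
1.329461e+00,1.246352e-01
1.364328e+00,1.214457e-01
1.400110e+00,1.183377e-01
1.436830e+00,1.153092e-01
1.474513e+00,1.123580e-01
1.513184e+00,1.094823e-01
1.552870e+00,1.066801e-01
1.593596e+00,1.039494e-01
1.635391e+00,1.012886e-01
1.678281e+00,9.869578e-02
1.722297e+00,9.616921e-02
1.767467e+00,9.370721e-02
1.813821e+00,9.130813e-02
1.861391e+00,8.897036e-02
1.910209e+00,8.669233e-02
1.960307e+00,8.447253e-02
2.011719e+00,8.230945e-02
2.064480e+00,8.020165e-02
2.118624e+00,7.814772e-02
2.174188e+00,7.614628e-02
2.231209e+00,7.419600e-02
2.289726e+00,7.229555e-02
2.349778e+00,7.044367e-02
2.411404e+00,6.863912e-02
2.474647e+00,6.688068e-02
2.539549e+00,6.516719e-02
2.606152e+00,6.349749e-02
2.674502e+00,6.187045e-02
2.744645e+00,6.028500e-02
2.816628e+00,5.874007e-02
2.890498e+00,5.723462e-02
2.966306e+00,5.576764e-02
3.044102e+00,5.433815e-02
3.123938e+00,5.294520e-02
3.205868e+00,5.158784e-02
3.289947e+00,5.026518e-02
3.376231e+00,4.897631e-02
3.464778e+00,4.772039e-02
3.555647e+00,4.649656e-02
3.648899e+00,4.530400e-02
3.744597e+00,4.414193e-02
3.842805e+00,4.300955e-02
3.943588e+00,4.190611e-02
4.047015e+00,4.083088e-02
4.153154e+00,3.978312e-02
4.262077e+00,3.876214e-02
4.373856e+00,3.776725e-02
4.488567e+00,3.679778e-02
4.606287e+00,3.585310e-02
4.727094e+00,3.493255e-02
4.851069e+00,3.403553e-02
4.978296e+00,3.316144e-02
5.108859e+00,3.230968e-02
5.242847e+00,3.147969e-02
5.380348e+00,3.067092e-02
5.521456e+00,2.988281e-02
5.666265e+00,2.911484e-02
5.814871e+00,2.836650e-02
5.967375e+00,2.763729e-02
6.123879e+00,2.692671e-02
6.284487e+00,2.623429e-02
6.449307e+00,2.555956e-02
6.618450e+00,2.490208e-02
6.792029e+00,2.426141e-02
6.970160e+00,2.363710e-02
7.152963e+00,2.302875e-02
7.340561e+00,2.243595e-02
7.533078e+00,2.185830e-02
7.730645e+00,2.129541e-02
7.933393e+00,2.074691e-02
8.141458e+00,2.021242e-02
8.354980e+00,1.969159e-02
8.574102e+00,1.918408e-02
8.798971e+00,1.868953e-02
9.029738e+00,1.820762e-02
9.266556e+00,1.773803e-02
9.509586e+00,1.728044e-02
9.758989e+00,1.683454e-02
1.001493e+01,1.640004e-02
1.027759e+01,1.597665e-02
1.054714e+01,1.556407e-02
1.082375e+01,1.516204e-02
1.110762e+01,1.477028e-02
1.139893e+01,1.438854e-02
1.169789e+01,1.401655e-02
1.200468e+01,1.365407e-02
1.231953e+01,1.330085e-02
1.264262e+01,1.295665e-02
1.297420e+01,1.262126e-02
1.331446e+01,1.229444e-02
1.366366e+01,1.197596e-02
1.402201e+01,1.166563e-02
1.438976e+01,1.136323e-02
1.476715e+01,1.106856e-02
1.515444e+01,1.078142e-02
1.555189e+01,1.050161e-02
1.595976e+01,1.022896e-02
1.637833e+01,9.963274e-03
1.680788e+01,9.704380e-03
1.724869e+01,9.452102e-03
1.770106e+01,9.206271e-03
1.816530e+01,8.966723e-03
1.864171e+01,8.733297e-03
1.913062e+01,8.505837e-03
1.963235e+01,8.284190e-03
2.014724e+01,8.068207e-03
2.067563e+01,7.857745e-03
2.121788e+01,7.652661e-03
2.177435e+01,7.452819e-03
2.234542e+01,7.258084e-03
2.293146e+01,7.068326e-03
2.353287e+01,6.883417e-03
2.415006e+01,6.703235e-03
2.478343e+01,6.527657e-03
2.543341e+01,6.356567e-03
2.610044e+01,6.189850e-03
2.678497e+01,6.027394e-03
2.748744e+01,5.869089e-03
2.820834e+01,5.714831e-03
2.894815e+01,5.564515e-03
2.970736e+01,5.418041e-03
3.048648e+01,5.275310e-03
3.128603e+01,5.136228e-03
3.210656e+01,5.000700e-03
3.294860e+01,4.868637e-03
3.381273e+01,4.739948e-03
3.469952e+01,4.614549e-03
3.560957e+01,4.492355e-03
3.654348e+01,4.373285e-03
3.750189e+01,4.257257e-03
3.848544e+01,4.144196e-03
3.949477e+01,4.034024e-03
4.053059e+01,3.926669e-03
4.159356e+01,3.822057e-03
4.268442e+01,3.720120e-03
4.380388e+01,3.620788e-03
4.495270e+01,3.523996e-03
4.613166e+01,3.429678e-03
4.734153e+01,3.337770e-03
4.858314e+01,3.248213e-03
4.985730e+01,3.160944e-03
5.000000e+01,3.151448e-03
5.116489e+01,3.075907e-03
5.250676e+01,2.993044e-03
5.388383e+01,2.912299e-03
5.529702e+01,2.833619e-03
5.674727e+01,2.756950e-03
5.823555e+01,2.682241e-03
5.976287e+01,2.609443e-03
6.133024e+01,2.538506e-03
6.293872e+01,2.469383e-03
6.458938e+01,2.402027e-03
6.628334e+01,2.336394e-03
6.802172e+01,2.272440e-03
6.980569e+01,2.210121e-03
7.163646e+01,2.149396e-03
7.351523e+01,2.090224e-03
7.544328e+01,2.032566e-03
7.742190e+01,1.976382e-03
7.945240e+01,1.921636e-03
8.153616e+01,1.868291e-03
8.367457e+01,1.816310e-03
8.586907e+01,1.765660e-03
8.812112e+01,1.716305e-03
9.043223e+01,1.668214e-03
9.280395e+01,1.621354e-03
9.523787e+01,1.575693e-03
9.773563e+01,1.531201e-03
1.002989e+02,1.487849e-03
1.029294e+02,1.445606e-03
1.056289e+02,1.404445e-03
1.083992e+02,1.364339e-03
1.112421e+02,1.325260e-03
1.141596e+02,1.287183e-03
1.171536e+02,1.250081e-03
1.202261e+02,1.213930e-03
1.233792e+02,1.178706e-03
1.266150e+02,1.144386e-03
1.299357e+02,1.110946e-03
1.333435e+02,1.078363e-03
1.368406e+02,1.046617e-03
1.404295e+02,1.015686e-03
1.441124e+02,9.855494e-04
1.478920e+02,9.561868e-04
1.517707e+02,9.275788e-04
1.557511e+02,8.997062e-04
1.598359e+02,8.725505e-04
1.640279e+02,8.460936e-04
1.683298e+02,8.203176e-04
1.727445e+02,7.952057e-04
1.772750e+02,7.707409e-04
1.819243e+02,7.469069e-04
1.866955e+02,7.236878e-04
1.915919e+02,7.010684e-04
1.966167e+02,6.790334e-04
2.017732e+02,6.575682e-04
2.070651e+02,6.366586e-04
2.124956e+02,6.162907e-04
2.180687e+02,5.964508e-04
2.237879e+02,5.771260e-04
2.296570e+02,5.583033e-04
2.356801e+02,5.399704e-04
2.418612e+02,5.221150e-04
2.482044e+02,5.047254e-04
2.547139e+02,4.877902e-04
2.613942e+02,4.712980e-04
2.682497e+02,4.552381e-04
2.752849e+02,4.395999e-04
2.825047e+02,4.243732e-04
2.899138e+02,4.095478e-04
2.975172e+02,3.951142e-04
3.053201e+02,3.810629e-04
3.133276e+02,3.673846e-04
3.215451e+02,3.540706e-04
3.299781e+02,3.411121e-04
3.386322e+02,3.285008e-04
3.475134e+02,3.162284e-04
3.500000e+02,3.129069e-04
3.566275e+02,3.042871e-04
3.659806e+02,2.926691e-04
3.755790e+02,2.813671e-04
3.854291e+02,2.703737e-04
3.955376e+02,2.596819e-04
4.059111e+02,2.492850e-04
4.165568e+02,2.391764e-04
4.274816e+02,2.293496e-04
4.386930e+02,2.197986e-04
4.501984e+02,2.105173e-04
4.620055e+02,2.014999e-04
4.741223e+02,1.927409e-04
4.865569e+02,1.842349e-04
4.993176e+02,1.759766e-04
5.110000e+02,1.688045e-04
5.124129e+02,1.679609e-04
5.258518e+02,1.601831e-04
5.396430e+02,1.526385e-04
5.537960e+02,1.453224e-04
5.683201e+02,1.382306e-04
5.832252e+02,1.313588e-04
5.985212e+02,1.247030e-04
6.142183e+02,1.182594e-04
6.303271e+02,1.120241e-04
6.468584e+02,1.059936e-04
6.638233e+02,1.001644e-04
6.812330e+02,9.453317e-05
6.990994e+02,8.909674e-05
7.174344e+02,8.385201e-05
7.362502e+02,7.879605e-05
7.555595e+02,7.392598e-05
7.753752e+02,6.923908e-05
7.957106e+02,6.473268e-05
8.165793e+02,6.040425e-05
8.379953e+02,5.625129e-05
8.599730e+02,5.227139e-05
8.825271e+02,4.846223e-05
9.056728e+02,4.482151e-05
9.294254e+02,4.134695e-05
9.538010e+02,3.803632e-05
9.788159e+02,3.488744e-05
1.004487e+03,3.189805e-05
1.030831e+03,2.906593e-05
1.057866e+03,2.638882e-05
1.085610e+03,2.386440e-05
1.114082e+03,2.149026e-05
1.143301e+03,1.926395e-05
1.173285e+03,1.718284e-05
1.204057e+03,1.524426e-05
1.235635e+03,1.344528e-05
1.268041e+03,1.178286e-05
1.301298e+03,1.025373e-05
1.335426e+03,8.854392e-06
1.370450e+03,7.581101e-06
1.406392e+03,6.429833e-06
1.443277e+03,5.396234e-06
1.481129e+03,4.475648e-06
1.519974e+03,3.663065e-06
1.559837e+03,2.953124e-06
1.600746e+03,2.340065e-06
1.642728e+03,1.817762e-06
1.685811e+03,1.379703e-06
1.730024e+03,1.019012e-06
1.775397e+03,7.284625e-07
1.821959e+03,5.005279e-07
1.869743e+03,3.274329e-07
1.918780e+03,2.012392e-07
1.969103e+03,1.139552e-07
2.020746e+03,5.768614e-08
2.073743e+03,2.481716e-08
2.128130e+03,8.251842e-09
2.183943e+03,1.713919e-09
2.241221e+03,1.127093e-10
2.300000e+03,0.000000e+00
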