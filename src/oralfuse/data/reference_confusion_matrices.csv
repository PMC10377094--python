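table,magnification,model,tp,fn,tn,fp,ac,mc,pr,se,sp,fs,note
df_softmax,100x,vgg16,142,11,143,4,95.0000,5.0000,97.2603,92.8105,97.2789,94.9833,
df_softmax,100x,vgg19,146,8,138,8,94.6667,5.3333,94.8052,94.8052,94.5205,94.8052,
df_softmax,100x,resnet18,134,19,146,1,93.3333,6.6667,99.2593,87.5817,99.3197,93.0556,
df_softmax,100x,resnet50,135,18,147,0,94.0000,6.0000,100,88.2353,100,93.7500,
df_softmax,100x,resnet101,141,12,143,4,94.6667,5.3333,97.2414,92.1569,97.2789,94.6309,
df_softmax,100x,densenet201,144,9,143,4,95.6667,4.3333,97.2973,94.1176,97.2789,95.6811,
df_softmax,400x,vgg16,141,7,144,8,95.0000,5.0000,94.6309,95.2703,94.7368,94.9495,
df_softmax,400x,vgg19,139,10,142,9,93.6667,6.3333,93.9189,93.2886,94.0397,93.6027,
df_softmax,400x,resnet18,140,8,138,14,92.6667,7.3333,90.9091,94.5946,90.7895,92.7152,
df_softmax,400x,resnet50,139,13,141,7,93.3333,6.6667,95.2055,91.4474,95.2703,93.2886,
df_softmax,400x,resnet101,141,7,142,10,94.3333,5.6667,93.3775,95.2703,93.4211,94.3144,
df_softmax,400x,densenet201,143,5,143,9,95.3333,4.6667,94.0789,96.6216,94.0789,95.3333,
vgg16,100x,softmax,142,11,143,4,95.0000,5.0000,97.2603,92.8105,97.2789,94.9833,
vgg16,100x,dt,142,6,142,10,94.6667,5.3333,93.4211,95.9459,93.4211,94.6667,
vgg16,100x,rf,144,7,138,11,94.0000,6.0000,92.9032,95.3642,92.6174,94.1176,
vgg16,100x,knn,140,9,144,7,94.6667,5.3333,95.2381,93.9597,95.3642,94.5946,
vgg16,100x,svm,141,10,143,6,94.6667,5.3333,95.9184,93.3775,95.9732,94.6309,
vgg16,400x,softmax,141,7,144,8,95.0000,5.0000,94.6309,95.2703,94.7368,94.9495,
vgg16,400x,dt,142,10,143,5,95.0000,5.0000,96.5986,93.4211,96.6216,94.9833,
vgg16,400x,rf,141,7,142,10,94.3333,5.6667,93.3775,95.2703,93.4211,94.3144,
vgg16,400x,knn,143,5,143,9,95.3333,4.6667,94.0789,96.6216,94.0789,95.3333,
vgg16,400x,svm,142,9,143,6,95.0000,5.0000,95.9459,94.0397,95.9732,94.9833,
densenet201,100x,softmax,144,9,143,4,95.6667,4.3333,97.2973,94.1176,97.2789,95.6811,
densenet201,100x,dt,143,8,140,9,94.3333,5.6667,94.0789,94.7020,93.9597,94.3894,
densenet201,100x,rf,142,9,144,5,95.3333,4.6667,96.5986,94.0397,96.6443,95.3020,
densenet201,100x,knn,144,8,144,4,96.0000,4.0000,97.2973,94.7368,97.2973,96.0000,
densenet201,100x,svm,143,4,143,10,95.3333,4.6667,93.4641,97.2789,93.4641,95.3333,
densenet201,400x,softmax,143,5,143,9,95.3333,4.6667,94.0789,96.6216,94.0789,95.3333,
densenet201,400x,dt,141,8,143,8,94.6667,5.3333,94.6309,94.6309,94.7020,94.6309,
densenet201,400x,rf,142,10,143,5,95.0000,5.0000,96.5986,93.4211,96.6216,94.9833,
densenet201,400x,knn,144,3,143,10,95.6667,4.3333,93.5065,97.9592,93.4641,95.6811,
densenet201,400x,svm,144,5,142,9,95.3333,4.6667,94.1176,96.6443,94.0397,95.3642,
ddf,100x,softmax,146,3,146,5,97.3333,2.6667,96.6887,97.9866,96.6887,97.3333,
ddf,100x,dt,146,6,145,3,97.0000,3.0000,97.9866,96.0526,97.9730,97.0100,
ddf,100x,rf,147,4,144,5,97.0000,3.0000,96.7105,97.3510,96.6443,97.0297,
ddf,100x,knn,147,2,146,5,97.6667,2.3333,96.7105,98.6577,96.6887,97.6744,
ddf,100x,svm,143,6,147,4,96.6667,3.3333,97.2789,95.9732,97.3510,96.6216,
ddf,400x,softmax,145,3,146,6,97.0000,3.0000,96.0265,97.9730,96.0526,96.9900,
ddf,400x,dt,145,6,147,2,97.3333,2.6667,98.6395,96.0265,98.6577,97.3154,
ddf,400x,rf,146,3,143,8,96.3333,3.6667,94.8052,97.9866,94.7020,96.3696,
ddf,400x,knn,146,7,146,1,97.3333,2.6667,99.3197,95.4248,99.3197,97.3333,
ddf,400x,svm,146,5,144,5,96.6667,3.3333,96.6887,96.6887,96.6443,96.6887,
edf,100x,softmax,145,4,144,7,96.3333,3.6667,95.3947,97.3154,95.3642,96.3455,
edf,100x,dt,145,6,145,4,96.6667,3.3333,97.3154,96.0265,97.3154,96.6667,
edf,100x,rf,146,3,143,8,96.3333,3.6667,94.8052,97.9866,94.7020,96.3696,
edf,100x,knn,145,6,146,3,97.0000,3.0000,97.9730,96.0265,97.9866,96.9900,
edf,100x,svm,145,4,145,6,96.6667,3.3333,96.0265,97.3154,96.0265,96.6667,
edf,400x,softmax,146,4,143,7,96.3333,3.6667,95.4248,97.3333,95.3333,96.3696,
edf,400x,dt,145,4,144,7,96.3333,3.6667,95.3947,97.3154,95.3642,96.3455,
edf,400x,rf,144,7,146,3,96.6667,3.3333,97.9592,95.3642,97.9866,96.6443,
edf,400x,knn,145,6,145,4,96.6667,3.3333,97.3154,96.0265,97.3154,96.6667,
edf,400x,svm,143,6,146,5,96.3333,3.6667,96.6216,95.9732,96.6887,96.2963,
ddf_hf,100x,softmax,147,2,149,2,98.6667,1.3333,98.6577,98.6577,98.6755,98.6577,
ddf_hf,100x,dt,148,0,149,3,99.0000,1.0000,98.0132,100,98.0263,98.9967,
ddf_hf,100x,rf,149,2,149,0,99.3333,0.6667,100,98.6755,100,99.3333,
ddf_hf,100x,knn,151,0,149,0,100,0.0000,100,100,100,100,
ddf_hf,100x,svm,150,1,149,0,99.6667,0.3333,100,99.3377,100,99.6678,
ddf_hf,400x,softmax,148,1,149,2,99.0000,1.0000,98.6667,99.3289,98.6755,98.9967,
ddf_hf,400x,dt,150,2,148,0,99.3333,0.6667,100,98.6842,100,99.3377,
ddf_hf,400x,rf,149,0,150,1,99.6667,0.3333,99.3333,100,99.3377,99.6656,
ddf_hf,400x,knn,150,0,150,0,100,1.0000,100,100,100,100,mc_typo
ddf_hf,400x,svm,148,1,151,0,99.6667,0.3333,100,99.3289,100,99.6633,
edf_hf,100x,softmax,149,0,149,2,99.3333,0.6667,98.6755,100,98.6755,99.3333,
edf_hf,100x,dt,148,2,149,1,99.0000,1.0000,99.3289,98.6667,99.3333,98.9967,
edf_hf,100x,rf,150,1,147,2,99.0000,1.0000,98.6842,99.3377,98.6577,99.0099,
edf_hf,100x,knn,149,2,149,0,99.3333,0.6667,100,98.6755,100,99.3333,
edf_hf,100x,svm,149,0,148,3,99.0000,1.0000,98.0263,100,98.0132,99.0033,
edf_hf,400x,softmax,149,1,148,2,99.0000,1.0000,98.6755,99.3333,98.6667,99.0033,
edf_hf,400x,dt,148,1,149,2,99.0000,1.0000,98.6667,99.3289,98.6755,98.9967,
edf_hf,400x,rf,149,2,149,0,99.3333,0.6667,100,98.6755,100,99.3333,
edf_hf,400x,knn,150,1,148,1,99.3333,0.6667,99.3377,99.3377,99.3289,99.3377,
edf_hf,400x,svm,149,0,148,3,99.0000,1.0000,98.0263,100,98.0132,99.0033,
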