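dataset,energy,technique,local_2_2,global_2_2,global_3_2,median_dd
Abdomen-TG244,6X,VMAT,93.7,99.8,100.0,1.1
Abdomen-TG244,6X,IMRT,86.3,97.9,99.4,1.5
Abdomen-TG244,15X,VMAT,94.8,99.8,100.0,1.1
Abdomen-TG244,15X,IMRT,89.2,98.0,99.4,1.1
Abdomen-TG244,10XFFF,VMAT,98.0,100.0,100.0,-0.2
Abdomen-TG244,10XFFF,IMRT,92.0,97.1,98.8,-0.6
HN-TG244,6X,VMAT,86.2,98.5,100.0,1.3
HN-TG244,6X,WFIMRT,78.3,95.4,98.9,2.3
HN-TG244,15X,VMAT,92.0,99.8,99.9,1.4
HN-TG244,15X,WFIMRT,81.8,95.8,99.0,2.3
HN-TG244,10XFFF,VMAT,92.1,98.4,99.3,-1.0
HN-TG244,10XFFF,WFIMRT,90.4,97.3,99.3,0.1
Anal-TG244,6X,VMAT,80.8,97.5,99.9,2.6
Anal-TG244,6X,WFIMRT,73.4,92.1,98.0,2.9
Anal-TG244,15X,VMAT,88.5,97.4,99.2,1.9
Anal-TG244,15X,WFIMRT,83.1,94.5,98.6,2.3
Anal-TG244,10XFFF,VMAT,92.1,98.9,99.6,-0.5
Anal-TG244,10XFFF,WFIMRT,91.8,98.1,99.5,0.7
Cshape-TG119,6X,VMAT,80.6,93.4,97.5,2.6
Cshape-TG119,6X,IMRT,85.4,90.4,95.3,2.4
Cshape-TG119,15X,VMAT,86.3,95.4,98.6,1.7
Cshape-TG119,15X,IMRT,86.5,92.1,95.6,0.8
Cshape-TG119,10XFFF,VMAT,91.2,98.4,99.7,-0.3
Cshape-TG119,10XFFF,IMRT,90.2,95.2,97.2,-0.3
HN-TG119,6X,VMAT,86.0,94.2,98.4,2.0
HN-TG119,6X,IMRT,89.0,94.1,98.4,1.0
HN-TG119,15X,VMAT,90.6,94.4,97.3,1.0
HN-TG119,15X,IMRT,92.5,95.4,98.1,0.5
HN-TG119,10XFFF,VMAT,91.2,95.3,97.4,-0.5
HN-TG119,10XFFF,IMRT,88.8,94.0,97.8,-1.1
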